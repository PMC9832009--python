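import numpy as np
import pytest

import dnbtrack as dt


def make_expr(values, gene_ids=None, sample_ids=None):
    """ExpressionMatrix from a plain array with auto-named axes."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    return dt.ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        sample_ids=sample_ids or [f"s{j}" for j in range(s)],
        values=values,
    )


@pytest.fixture(scope="session")
def default_timecourse():
    """One default synthetic time course shared by read-only tests."""
    cfg = dt.SyntheticConfig(seed=11)
    counts, design, truth = dt.generate_timecourse(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def default_expression(default_timecourse):
    _cfg, counts, design, truth = default_timecourse
    return dt.normalize_rle(counts), design, truth


def lineage_subspace_for(cfg, expr):
    """ADC-vs-SCC differential subspace from an independent synthetic cohort.

    Mirrors the study design, where the candidate gene space for the
    network scan is the lineage-differential gene list estimated on an
    external two-lineage tumor cohort.
    """
    from dnbtrack.signatures import lineage_subspace

    fractions = np.array([0.0] * 30 + [1.0] * 30)
    cohort, _truth = dt.generate_adsc_cohort(60, fractions, cfg)
    sub = lineage_subspace(cohort, cohort.sample_ids[:30], cohort.sample_ids[30:])
    present = set(expr.gene_ids)
    return [g for g in sub if g in present]
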
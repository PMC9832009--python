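"""Gene-set signature scores, differential gene sets, and AST scoring.

Two signature conventions are implemented, matching their respective uses:

* ``zscore_signature`` — the combined-z ("z-score") gene-set method:
  each member gene is standardized across samples and the per-sample score
  is the sum of member z-values divided by sqrt(k).  Used for pathway and
  TF-target signatures.
* ``ast_score`` — lineage component scores as the plain mean of
  standardized expression over a direction-resolved set: the ADC score
  averages z-values of genes upregulated in adenocarcinoma, the SCC score
  those upregulated in squamous carcinoma, and the AST
  (adeno-to-squamous-transdifferentiation) score is SCC - ADC per sample,
  ordering tumors from ADC-like to SCC-like.

Differential gene sets are derived with a per-gene Welch t-test on
normalized log2 values with Benjamini-Hochberg adjustment and a fold-change
gate (default: fold change > 2 and adjusted P < 0.001) — a simplified,
pluggable stand-in for count-model differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .io import ExpressionMatrix, GeneSet

__all__ = [
    "SignatureScore",
    "zscore_signature",
    "de_genes",
    "DEResult",
    "ast_score",
    "ASTResult",
    "correlate_with_ast",
]


@dataclass
class SignatureScore:
    """Per-sample scalar scores for one gene set."""

    set_name: str
    sample_ids: list[str]
    scores: np.ndarray
    method: str  # {gsva_z, mean_z, ast}

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise AnalysisError("one score per sample required")
        if not np.all(np.isfinite(self.scores)):
            raise AnalysisError("scores must be finite")
        if self.method not in ("gsva_z", "mean_z", "ast"):
            raise AnalysisError(f"unknown method {self.method!r}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.set_name)


def _member_zvalues(e: ExpressionMatrix, s: GeneSet) -> np.ndarray:
    """z-standardize present member genes across samples (zero-variance -> 0)."""
    present = [g for g in s.members if g in set(e.gene_ids)]
    if not present:
        missing = s.members[:5]
        raise AnalysisError(
            f"no member of gene set {s.name!r} present in the matrix (e.g. {missing})"
        )
    if len(e.sample_ids) < 2:
        raise AnalysisError("signature scoring needs >= 2 samples")
    idx = e.gene_index(present)
    x = e.values[idx]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def zscore_signature(e: ExpressionMatrix, s: GeneSet) -> SignatureScore:
    """Combined-z gene-set score: sum of member z-values / sqrt(k present)."""
    z = _member_zvalues(e, s)
    scores = z.sum(axis=0) / np.sqrt(z.shape[0])
    return SignatureScore(
        set_name=s.name, sample_ids=list(e.sample_ids), scores=scores, method="gsva_z"
    )


def mean_z_signature(e: ExpressionMatrix, s: GeneSet) -> SignatureScore:
    """Plain mean of standardized member expression (lineage component score)."""
    z = _member_zvalues(e, s)
    return SignatureScore(
        set_name=s.name, sample_ids=list(e.sample_ids), scores=z.mean(axis=0), method="mean_z"
    )


@dataclass
class DEResult:
    """Direction-resolved differential gene sets plus the full per-gene table."""

    up: GeneSet | None
    down: GeneSet | None
    table: pd.DataFrame


def de_genes(
    e: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.001,
    set_prefix: str = "DE",
) -> DEResult:
    """Welch-t differential genes between two sample groups on log2 values.

    A gene is "up" iff its mean log2 fold change (A minus B) exceeds
    log2(fc_threshold) and its BH-adjusted p-value is below ``alpha``;
    mirrored for "down".  Genes with zero variance in both groups are
    assigned p = 1.  Empty result sets are returned as ``None``.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise AnalysisError("each group needs >= 3 samples")
    xa = e.subset_samples(group_a).values
    xb = e.subset_samples(group_b).values
    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    _rej, p_adj, _a, _b = multipletests(p, method="fdr_bh")
    log_fc_gate = np.log2(fc_threshold)
    up_mask = (lfc > log_fc_gate) & (p_adj < alpha)
    down_mask = (lfc < -log_fc_gate) & (p_adj < alpha)
    table = pd.DataFrame(
        {
            "gene_id": e.gene_ids,
            "log2_fc": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(up_mask, "up", np.where(down_mask, "down", "ns")),
        }
    )
    genes = np.array(e.gene_ids)
    up = (
        GeneSet(name=f"{set_prefix}_up", members=list(genes[up_mask]), direction="up")
        if up_mask.any()
        else None
    )
    down = (
        GeneSet(name=f"{set_prefix}_down", members=list(genes[down_mask]), direction="down")
        if down_mask.any()
        else None
    )
    return DEResult(up=up, down=down, table=table)


def lineage_subspace(
    e: ExpressionMatrix,
    adc_samples: list[str],
    scc_samples: list[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.001,
) -> list[str]:
    """Lineage-differential candidate subspace for the DNB scan.

    The tipping-point analysis is constrained to genes differential between
    the adenomatous and squamous lineages, estimated on an independent
    two-lineage cohort.  Returns the union of up- and down-regulated genes
    at the given thresholds, in matrix order.
    """
    res = de_genes(e, adc_samples, scc_samples, fc_threshold=fc_threshold, alpha=alpha)
    chosen = set()
    for s in (res.up, res.down):
        if s is not None:
            chosen.update(s.members)
    return [g for g in e.gene_ids if g in chosen]


@dataclass
class ASTResult:
    """ADC, SCC and AST scores plus the ADC-like -> SCC-like sample ordering."""

    adc: SignatureScore
    scc: SignatureScore
    ast: SignatureScore
    ordering: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.ast.sample_ids,
                "adc_score": self.adc.scores,
                "scc_score": self.scc.scores,
                "ast_score": self.ast.scores,
            }
        )


def ast_score(e: ExpressionMatrix, adc_up: GeneSet, scc_up: GeneSet) -> ASTResult:
    """AST score = SCC score - ADC score per sample.

    Component scores are means of standardized expression over the genes
    upregulated in each lineage.  The returned ordering ranks samples from
    most ADC-like to most SCC-like (ascending AST, ties by sample id).
    """
    adc = mean_z_signature(e, adc_up)
    scc = mean_z_signature(e, scc_up)
    ast = SignatureScore(
        set_name=f"AST({scc_up.name}-{adc_up.name})",
        sample_ids=list(e.sample_ids),
        scores=scc.scores - adc.scores,
        method="ast",
    )
    order = sorted(range(len(ast.scores)), key=lambda i: (ast.scores[i], ast.sample_ids[i]))
    return ASTResult(adc=adc, scc=scc, ast=ast, ordering=[ast.sample_ids[i] for i in order])


def correlate_with_ast(sig: SignatureScore, ast: SignatureScore) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between a signature and the AST score.

    Negative r reads directly as "negatively correlated with the AST score"
    (i.e. the signature decays as tumors become squamous).  A zero-variance
    score vector yields (nan, nan).
    """
    if sig.sample_ids != ast.sample_ids:
        raise AnalysisError("signatures must cover the same samples in the same order")
    if len(sig.scores) < 3:
        raise AnalysisError("correlation needs >= 3 samples")
    if np.std(sig.scores) == 0 or np.std(ast.scores) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(sig.scores, ast.scores)
    return float(r), float(p)
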
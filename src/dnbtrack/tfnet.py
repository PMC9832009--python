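"""Mutual-suppression ("Yin-Yang") analysis of lineage TF programs.

Lineage identity in lung tumors is maintained by antagonistic
transcription-factor programs: adenocarcinoma (ADC) TFs such as NKX2-1 and
FOXA2 versus squamous (SCC) TFs such as TP63 and SOX2.  If the programs
mutually suppress each other, the targets of each family should be
over-represented among the genes the opposite program tunes down.

The statistical primitive is a one-sided Fisher-exact / hypergeometric
enrichment test of the overlap between two gene sets inside an explicit
gene universe; on top of it sit a per-TF enrichment ranking and the
counteraction-network construction with its mutual-suppression verdict.
The universe choice dominates every Fisher p-value and is therefore always
an explicit argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .io import GeneSet

__all__ = [
    "OverlapTestResult",
    "overlap_test",
    "tf_enrichment",
    "YinYangResult",
    "build_yinyang_network",
]


@dataclass
class OverlapTestResult:
    """2x2 overlap table with odds ratio and enrichment p-value."""

    overlap: int
    a_only: int
    b_only: int
    neither: int
    universe_size: int
    odds_ratio: float
    p_value: float
    continuity_corrected: bool = False
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        counts = (self.overlap, self.a_only, self.b_only, self.neither)
        if any(c < 0 for c in counts) or sum(counts) != self.universe_size:
            raise AnalysisError("2x2 counts must be nonnegative and sum to the universe")
        if not 0 < self.p_value <= 1:
            raise AnalysisError("p-value must lie in (0, 1]")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.overlap, self.a_only], [self.b_only, self.neither]])


def overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    two_sided: bool = False,
) -> OverlapTestResult:
    """Fisher-exact test of the overlap of two gene sets within a universe.

    Default is the one-sided enrichment tail, the hypergeometric
    ``P(X >= observed overlap)``.  The odds ratio comes from the 2x2 table;
    a 0.5 continuity correction is applied (and flagged) only when a cell
    is zero.
    """
    uni = set(universe)
    if not uni:
        raise AnalysisError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= uni or not b <= uni:
        stray = sorted((a | b) - uni)
        raise AnalysisError(f"sets must be subsets of the universe; stray genes: {stray[:5]}")
    n = len(uni)
    k = len(a & b)
    a_only, b_only = len(a) - k, len(b) - k
    neither = n - len(a) - len(b) + k

    if two_sided:
        _or, p = stats.fisher_exact([[k, a_only], [b_only, neither]], alternative="two-sided")
    else:
        # enrichment tail: draw |B| genes, |A| marked, observe >= k marked
        p = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)

    cells = np.array([k, a_only, b_only, neither], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    odds = float(cells[0] * cells[3] / (cells[1] * cells[2]))
    return OverlapTestResult(
        overlap=k,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        universe_size=n,
        odds_ratio=odds,
        p_value=p,
        continuity_corrected=corrected,
    )


def tf_enrichment(
    query: GeneSet,
    tf_targets: Mapping[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Rank TFs by enrichment of their targets in a query gene set.

    One overlap test per TF (targets restricted to the universe), BH
    adjustment across all TFs, sorted by descending -log10 p, ties broken
    by descending overlap then TF id.
    """
    if not tf_targets:
        raise AnalysisError("empty TF target map")
    uni = set(universe)
    qset = set(query.members)
    if not qset <= uni:
        raise AnalysisError("query set must be a subset of the universe")
    rows = []
    for tf, targets in tf_targets.items():
        res = overlap_test(targets & uni, qset, uni)
        rows.append(
            {
                "tf": tf,
                "n_targets": len(targets & uni),
                "overlap": res.overlap,
                "odds_ratio": res.odds_ratio,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    _rej, p_adj, _a, _b = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["p_adj"] = p_adj
    out["neg_log10_p"] = -np.log10(out["p"])
    out = out.sort_values(
        by=["neg_log10_p", "overlap", "tf"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out


@dataclass
class YinYangResult:
    """Counteraction network between two lineage TF families."""

    graph: nx.DiGraph
    adc_family_test: OverlapTestResult
    scc_family_test: OverlapTestResult
    mutual_suppression: bool
    alpha: float

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "src": u,
                "dst": v,
                "odds_ratio": d["odds_ratio"],
                "p": d["p"],
                "p_adj": d["p_adj"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def build_yinyang_network(
    adc_tfs: Mapping[str, set[str]],
    scc_tfs: Mapping[str, set[str]],
    induced: GeneSet,
    repressed: GeneSet,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> YinYangResult:
    """Test for mutual suppression between the ADC and SCC TF programs.

    ``repressed`` holds the genes tuned down across the transition (the
    ADC program's output, shut off by the SCC program); ``induced`` the
    genes switched on (the SCC program's output).  Mutual suppression
    requires both cross-family enrichments — pooled ADC-family targets in
    ``repressed`` AND pooled SCC-family targets in ``induced`` — to pass
    ``alpha`` after BH adjustment over the two family tests.  Per-TF edges
    (TF -> opposing-program gene set) are weighted by overlap-test odds
    ratios.
    """
    if not adc_tfs or not scc_tfs:
        raise AnalysisError("both TF families must be nonempty")
    if set(adc_tfs) & set(scc_tfs):
        raise AnalysisError("TF families must be disjoint")
    uni = set(universe)

    pooled_adc = set().union(*adc_tfs.values()) & uni
    pooled_scc = set().union(*scc_tfs.values()) & uni
    adc_test = overlap_test(pooled_adc, set(repressed.members) & uni, uni)
    scc_test = overlap_test(pooled_scc, set(induced.members) & uni, uni)
    _rej, fam_adj, _a, _b = multipletests(
        [adc_test.p_value, scc_test.p_value], method="fdr_bh"
    )
    adc_test.p_adjusted = float(fam_adj[0])
    scc_test.p_adjusted = float(fam_adj[1])
    verdict = bool(fam_adj[0] < alpha and fam_adj[1] < alpha)

    g = nx.DiGraph()
    edge_rows = []
    for tf, targets in adc_tfs.items():
        res = overlap_test(targets & uni, set(repressed.members) & uni, uni)
        edge_rows.append((tf, repressed.name, res))
    for tf, targets in scc_tfs.items():
        res = overlap_test(targets & uni, set(induced.members) & uni, uni)
        edge_rows.append((tf, induced.name, res))
    edge_p = [r.p_value for _u, _v, r in edge_rows]
    _rej, edge_adj, _a, _b = multipletests(edge_p, method="fdr_bh")
    for (tf, target_set, res), padj in zip(edge_rows, edge_adj):
        g.add_edge(tf, target_set, odds_ratio=res.odds_ratio, p=res.p_value, p_adj=float(padj))

    return YinYangResult(
        graph=g,
        adc_family_test=adc_test,
        scc_family_test=scc_test,
        mutual_suppression=verdict,
        alpha=alpha,
    )
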
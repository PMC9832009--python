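"""Dynamic network biomarker (DNB) detection of a tipping point.

As a system approaches a critical transition, DNB theory predicts that a
group of genes (the dominant module) emerges for which, simultaneously,

1. the mean absolute within-module Pearson correlation (``PCC_i``) rises,
2. the mean absolute correlation between module genes and the rest of the
   candidate subspace (``PCC_o``) falls, and
3. the mean within-timepoint standard deviation of module genes (``SD_i``)
   rises sharply.

The composite criticality index combines the three:

    CI = (PCC_i / PCC_o) * SD_i

Per time point, a correlation network over replicates is built, candidate
modules are enumerated deterministically from an average-linkage dendrogram
on the distance ``1 - |PCC|``, CI is evaluated for every candidate, and the
maximum-CI module is the dominant group.  The time point where the dominant
CI peaks is the estimated tipping point.  When replicates are too few for
per-timepoint correlation, a sliding window pools consecutive time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import AnalysisError, ConfigError, InsufficientReplicatesError
from .io import ExpressionMatrix, TimeCourseDesign

__all__ = [
    "CorrelationNetwork",
    "GeneModule",
    "CIProfile",
    "pairwise_pcc",
    "detect_modules",
    "composite_index",
    "dnb_scan",
    "sliding_window_scan",
]

PCC_O_EPSILON = 1e-6


@dataclass
class CorrelationNetwork:
    """Gene-gene Pearson correlations across replicates at one time point."""

    gene_ids: list[str]
    matrix: np.ndarray
    time_label: float | str = ""
    zero_variance_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.gene_ids)
        if self.matrix.shape != (n, n):
            raise AnalysisError("correlation matrix shape mismatch")


@dataclass(frozen=True)
class GeneModule:
    """A candidate DNB module: a unique, sorted tuple of member gene ids."""

    members: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise AnalysisError("a module needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise AnalysisError("module members must be unique")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CIProfile:
    """Per-timepoint composite-index results of a DNB scan."""

    time_points: list[float]
    pcc_in: list[float]
    pcc_out: list[float]
    sd_in: list[float]
    ci: list[float]
    dominant_modules: list[GeneModule]
    tipping_point_index: int
    module_tables: list[pd.DataFrame] = field(default_factory=list)

    @property
    def tipping_point_time(self) -> float:
        return self.time_points[self.tipping_point_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_weeks": self.time_points,
                "pcc_in": self.pcc_in,
                "pcc_out": self.pcc_out,
                "sd_in": self.sd_in,
                "ci": self.ci,
                "module_size": [len(m) for m in self.dominant_modules],
                "is_tipping_point": [
                    i == self.tipping_point_index for i in range(len(self.time_points))
                ],
            }
        )


def pairwise_pcc(
    e: ExpressionMatrix,
    samples_at_timepoint: Sequence[str],
    time_label: float | str = "",
    min_replicates: int = 3,
) -> CorrelationNetwork:
    """Pearson correlation across the replicate axis for every gene pair.

    Genes with zero variance across the replicates get correlation 0 to all
    others and are flagged in ``zero_variance_genes``.
    """
    if len(samples_at_timepoint) < min_replicates:
        raise InsufficientReplicatesError(
            f"{len(samples_at_timepoint)} replicates at {time_label!r} "
            f"(minimum {min_replicates}); consider sliding_window_scan"
        )
    sub = e.subset_samples(list(samples_at_timepoint))
    x = sub.values
    sd = x.std(axis=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationNetwork(
        gene_ids=list(e.gene_ids),
        matrix=r,
        time_label=time_label,
        zero_variance_genes=frozenset(np.array(e.gene_ids)[zero_var]),
    )


def _mean_abs_within(abs_r: np.ndarray, idx: np.ndarray) -> float:
    k = len(idx)
    if k < 2:
        return 0.0
    sub = abs_r[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (k * (k - 1)))


def _cluster_tree_members(Z: np.ndarray, n: int) -> list[tuple[int, frozenset[int]]]:
    """Leaf sets of every internal dendrogram node, bottom-up."""
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out: list[tuple[int, frozenset[int]]] = []
    for i, (a, b, _h, _c) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members.append(merged)
        out.append((i, merged))
    return out


def detect_modules(
    net: CorrelationNetwork, min_size: int = 5, max_size: int = 200
) -> list[GeneModule]:
    """Enumerate candidate modules from a deterministic hierarchical clustering.

    Average-linkage clustering on the distance ``1 - |PCC|``; the dendrogram
    is cut at every merge height and each resulting cluster whose size lies
    in ``[min_size, max_size]`` is emitted once.  Output is ordered by
    decreasing mean within-cluster ``|PCC|``, ties broken by the
    lexicographically smallest member id, so the result is fully
    deterministic.
    """
    if min_size < 2 or max_size < min_size:
        raise ConfigError("need 2 <= min_size <= max_size")
    n = len(net.gene_ids)
    if n < min_size:
        return []
    abs_r = np.abs(net.matrix)
    dist = 1.0 - abs_r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    Z = linkage(squareform(dist, checks=False), method="average")

    genes = np.array(net.gene_ids)
    seen: set[frozenset[int]] = set()
    scored: list[tuple[float, tuple[str, ...], str]] = []
    for node, members in _cluster_tree_members(Z, n):
        if not (min_size <= len(members) <= max_size) or members in seen:
            continue
        seen.add(members)
        idx = np.fromiter(members, dtype=int)
        cohesion = _mean_abs_within(abs_r, idx)
        member_ids = tuple(sorted(genes[idx]))
        scored.append((cohesion, member_ids, f"average-linkage node {node}"))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [GeneModule(members=m, provenance=p) for _c, m, p in scored]


def composite_index(
    m: GeneModule,
    e: ExpressionMatrix,
    samples_at_timepoint: Sequence[str],
    epsilon: float = PCC_O_EPSILON,
    min_replicates: int = 3,
) -> tuple[float, float, float, float]:
    """Compute (PCC_i, PCC_o, SD_i, CI) for one module at one time point.

    ``PCC_i`` is the mean absolute correlation over unordered module pairs,
    ``PCC_o`` the mean absolute correlation over module x non-module pairs,
    ``SD_i`` the mean within-timepoint standard deviation (ddof=1) of module
    genes, and ``CI = (PCC_i / max(PCC_o, epsilon)) * SD_i``.
    """
    if len(m) >= len(e.gene_ids):
        raise AnalysisError("module equals the whole subspace; PCC_o undefined")
    if not samples_at_timepoint:
        raise AnalysisError("empty time point")
    net = pairwise_pcc(e, samples_at_timepoint, min_replicates=min_replicates)
    idx = e.gene_index(m.members)
    sub = e.subset_samples(list(samples_at_timepoint))
    sd_vec = sub.values.std(axis=1, ddof=1)
    return _ci_from_network(np.abs(net.matrix), sd_vec, idx, epsilon)


def _ci_from_network(
    abs_r: np.ndarray, sd_vec: np.ndarray, idx: np.ndarray, epsilon: float = PCC_O_EPSILON
) -> tuple[float, float, float, float]:
    n = abs_r.shape[0]
    k = len(idx)
    pcc_i = _mean_abs_within(abs_r, idx)
    row_sums = abs_r[idx, :].sum()  # over module rows, all columns
    within_sum = abs_r[np.ix_(idx, idx)].sum()
    pcc_o = float((row_sums - within_sum) / (k * (n - k)))
    sd_i = float(sd_vec[idx].mean())
    ci = (pcc_i / max(pcc_o, epsilon)) * sd_i
    return pcc_i, pcc_o, sd_i, ci


def _top_variable_genes(e: ExpressionMatrix, k: int) -> list[str]:
    var = e.values.var(axis=1)
    order = np.lexsort((np.array(e.gene_ids), -var))
    return [e.gene_ids[i] for i in order[:k]]


def _scan_groups(
    e: ExpressionMatrix,
    groups: list[tuple[float, list[str]]],
    subspace: Sequence[str] | None,
    min_size: int,
    max_size: int,
    top_k_variable: int,
    epsilon: float,
    min_replicates: int,
) -> CIProfile:
    if subspace is None:
        subspace = _top_variable_genes(e, top_k_variable)
    subspace = list(dict.fromkeys(subspace))
    idx_sub = e.gene_index(subspace)
    sub_expr = ExpressionMatrix(
        gene_ids=[e.gene_ids[i] for i in idx_sub],
        sample_ids=list(e.sample_ids),
        values=e.values[idx_sub, :],
    )
    gene_pos = {g: i for i, g in enumerate(sub_expr.gene_ids)}

    times: list[float] = []
    pcc_in: list[float] = []
    pcc_out: list[float] = []
    sd_in: list[float] = []
    cis: list[float] = []
    dominant: list[GeneModule] = []
    tables: list[pd.DataFrame] = []

    for label, samples in groups:
        net = pairwise_pcc(sub_expr, samples, time_label=label, min_replicates=min_replicates)
        abs_r = np.abs(net.matrix)
        sd_vec = sub_expr.subset_samples(samples).values.std(axis=1, ddof=1)
        modules = detect_modules(net, min_size=min_size, max_size=max_size)
        if not modules:
            raise AnalysisError(
                f"no candidate module of size in [{min_size}, {max_size}] at {label!r}"
            )
        rows = []
        best: tuple[float, int] | None = None
        stats: list[tuple[float, float, float, float]] = []
        for mi, mod in enumerate(modules):
            if len(mod) >= len(sub_expr.gene_ids):
                continue
            midx = np.fromiter((gene_pos[g] for g in mod.members), dtype=int)
            pi, po, sdi, ci = _ci_from_network(abs_r, sd_vec, midx, epsilon)
            stats.append((pi, po, sdi, ci))
            rows.append(
                {"rank": mi, "size": len(mod), "pcc_in": pi, "pcc_out": po, "sd_in": sdi, "ci": ci}
            )
            if best is None or ci > best[0]:
                best = (ci, mi)
        if best is None:
            raise AnalysisError(
                f"every candidate module at {label!r} spans the whole subspace; "
                "PCC_o is undefined — enlarge the subspace or lower max_size"
            )
        _, bi = best
        pi, po, sdi, ci = stats[bi]
        times.append(label)
        pcc_in.append(pi)
        pcc_out.append(po)
        sd_in.append(sdi)
        cis.append(ci)
        dominant.append(modules[bi])
        tables.append(pd.DataFrame(rows))

    tipping = int(np.argmax(cis))  # np.argmax returns the first (earliest) maximum
    return CIProfile(
        time_points=times,
        pcc_in=pcc_in,
        pcc_out=pcc_out,
        sd_in=sd_in,
        ci=cis,
        dominant_modules=dominant,
        tipping_point_index=tipping,
        module_tables=tables,
    )


def dnb_scan(
    e: ExpressionMatrix,
    d: TimeCourseDesign,
    subspace: Sequence[str] | None = None,
    min_size: int = 5,
    max_size: int = 200,
    top_k_variable: int = 2000,
    epsilon: float = PCC_O_EPSILON,
) -> CIProfile:
    """Scan every time point for the dominant (max-CI) module.

    ``subspace`` restricts the analysis to a candidate gene list (e.g.
    lineage-differential genes); when absent, the ``top_k_variable`` most
    variable genes are used.  The tipping point is the argmax of the
    dominant CI over time, ties broken toward the earliest time point.
    """
    d.validate_against(e)
    groups = [(t, d.samples_at(t)) for t in d.time_points]
    for t, samples in groups:
        if len(samples) < d.min_replicates:
            raise InsufficientReplicatesError(
                f"time point {t} has {len(samples)} replicates "
                f"(minimum {d.min_replicates}); use sliding_window_scan"
            )
    return _scan_groups(
        e, groups, subspace, min_size, max_size, top_k_variable, epsilon, d.min_replicates
    )


def sliding_window_scan(
    e: ExpressionMatrix,
    d: TimeCourseDesign,
    subspace: Sequence[str] | None = None,
    window: int = 3,
    min_size: int = 5,
    max_size: int = 200,
    top_k_variable: int = 2000,
    epsilon: float = PCC_O_EPSILON,
) -> CIProfile:
    """DNB scan pooling replicates of ``window`` consecutive time points.

    Pooling artificially increases the per-evaluation sample count, making
    correlation estimation possible with few replicates per time point.
    Each window is labeled by its central time point (the later of the two
    central points for an even window).  ``window=1`` is identical to
    ``dnb_scan``.
    """
    d.validate_against(e)
    times = d.time_points
    if window < 1:
        raise ConfigError("window must be >= 1")
    if window > len(times):
        raise ConfigError(f"window {window} exceeds {len(times)} time points")
    groups: list[tuple[float, list[str]]] = []
    for i in range(len(times) - window + 1):
        span = times[i : i + window]
        label = span[window // 2]
        samples = [s for t in span for s in d.samples_at(t)]
        groups.append((label, samples))
    for label, samples in groups:
        if len(samples) < d.min_replicates:
            raise InsufficientReplicatesError(
                f"window centered at {label} pools only {len(samples)} samples"
            )
    return _scan_groups(
        e, groups, subspace, min_size, max_size, top_k_variable, epsilon, d.min_replicates
    )
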
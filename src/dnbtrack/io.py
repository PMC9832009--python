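"""Input/output and normalization.

Reads gene x sample count matrices (TSV/CSV), time-course design tables
(CSV), gene sets (GMT) and transcription-factor target maps (two-column
TSV), and produces the normalized log2 expression matrix every downstream
stage consumes.

Normalization follows the relative-log-expression (RLE, median-of-ratios)
convention: per-sample normalization factors are estimated on
library-size-normalized proportions, rescaled to geometric mean 1, and the
effective library size of a sample is ``library_size * factor``.  Expression
values are ``log2(1e6 * count / effective_library_size + pseudocount)``,
i.e. log2 reads-per-million with a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError, NormalizationError

PHENOTYPES = ("NL", "AAH", "ADC", "SCC", "other")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise FormatError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(self.counts < 0):
            raise FormatError("counts must be nonnegative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise FormatError("counts must be integers")
        self.counts = np.round(self.counts).astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Normalized log2-scale abundances (log2 RPM + pseudocount), genes x samples.

    ``size_factors`` are the geometric-mean-1 RLE normalization factors;
    ``effective_lib_sizes`` the factor-adjusted library sizes actually used
    as the per-sample denominator.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray | None = None
    effective_lib_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("expression matrix shape mismatch")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise FormatError("size factors must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Integer row positions of ``gene_ids``; unknown ids raise."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise AnalysisError(f"genes absent from matrix: {missing[:5]}")
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise AnalysisError(f"samples absent from matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            size_factors=None if self.size_factors is None else self.size_factors[idx],
            effective_lib_sizes=(
                None if self.effective_lib_sizes is None else self.effective_lib_sizes[idx]
            ),
        )


@dataclass
class TimeCourseDesign:
    """Sample -> (time point in weeks, phenotype, replicate) mapping."""

    table: pd.DataFrame
    min_replicates: int = 3

    REQUIRED = ("sample_id", "time_weeks", "phenotype", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        t = self.table
        _check_unique(list(t["sample_id"]), "sample ids")
        if (t["time_weeks"] < 0).any():
            raise FormatError("time_weeks must be nonnegative")
        bad = set(t["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise FormatError(f"unknown phenotype labels: {sorted(bad)}")
        if (t["replicate"] < 1).any():
            raise FormatError("replicate indices must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def time_points(self) -> list[float]:
        """Sorted unique time points in weeks."""
        return sorted(self.table["time_weeks"].unique())

    def samples_at(self, time_weeks: float) -> list[str]:
        mask = self.table["time_weeks"] == time_weeks
        return list(self.table.loc[mask, "sample_id"])

    def validate_against(self, matrix: CountMatrix | ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise FormatError(f"design samples absent from matrix: {sorted(missing)[:5]}")


@dataclass
class GeneSet:
    """A named gene set with an optional regulation direction."""

    name: str
    members: list[str]
    direction: str = "unsigned"  # {up, down, unsigned}
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")
        # dedupe, preserving first-occurrence order
        self.members = list(dict.fromkeys(self.members))
        if self.direction not in ("up", "down", "unsigned"):
            raise FormatError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene-major counts table (first column gene ids, header row)."""
    df = _read_table(path)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric counts") from exc
    if np.any(~np.isfinite(values)):
        raise FormatError(f"{path}: missing or non-finite counts")
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=values,
    )


def write_counts(c: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    c.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_design(path: str | Path, min_replicates: int = 3) -> TimeCourseDesign:
    """Read a sample design CSV with columns sample_id,time_weeks,phenotype,replicate."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    return TimeCourseDesign(table=df, min_replicates=min_replicates)


def write_design(d: TimeCourseDesign, path: str | Path) -> None:
    d.table.to_csv(path, index=False)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, tab-separated members)."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name=name, members=members, description=desc))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_tf_targets(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (tf, target) TSV into a TF -> target-set map."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    if not mapping:
        raise FormatError(f"{path}: empty TF target map")
    return mapping


def write_tf_targets(mapping: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(mapping):
            for target in sorted(mapping[tf]):
                fh.write(f"{tf}\t{target}\n")


# ---------------------------------------------------------------------------
# normalization


def rle_norm_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios (RLE) normalization factors, geometric mean 1.

    Ratios are formed on library-size-normalized proportions against the
    per-gene geometric mean across samples; genes with a zero in any sample
    are excluded from factor estimation (their geometric mean is zero) but
    retained in the matrix.
    """
    counts = np.asarray(counts, dtype=float)
    lib_sizes = counts.sum(axis=0)
    if np.any(lib_sizes == 0):
        bad = list(np.where(lib_sizes == 0)[0])
        raise NormalizationError(f"samples with all-zero counts at columns {bad}")
    props = counts / lib_sizes
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise NormalizationError("no gene has nonzero counts in every sample")
    logp = np.log(props[positive])
    log_geomean = logp.mean(axis=1)
    log_factors = np.median(logp - log_geomean[:, None], axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return np.exp(log_factors)


def normalize_rle(c: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Normalize counts to log2(RPM + pseudocount) with RLE size factors."""
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be positive")
    factors = rle_norm_factors(c.counts)
    lib_sizes = c.counts.sum(axis=0).astype(float)
    effective = lib_sizes * factors
    rpm = 1e6 * c.counts / effective
    values = np.log2(rpm + pseudocount)
    return ExpressionMatrix(
        gene_ids=list(c.gene_ids),
        sample_ids=list(c.sample_ids),
        values=values,
        size_factors=factors,
        effective_lib_sizes=effective,
    )
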
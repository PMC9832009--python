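"""Synthetic temporal count data with a planted critical transition.

The generator emulates the study conditions every downstream stage is
tested against:

* multi-timepoint bulk RNA-seq counts with replicates, negative-binomial
  noise on top of a Gaussian latent log-expression model;
* a planted gene module whose within-module correlation and standard
  deviation spike at one time point (the tipping point ``t_star``) while
  its correlation to outside genes drops — the dynamic-network-biomarker
  (DNB) signature;
* adenocarcinoma (ADC) markers that switch off and squamous (SCC) markers
  that switch on sigmoidally across the transition;
* a tumor-cohort mixture of ADC-like and SCC-like expression, with a
  planted "Wnt-like" signature that decays with squamous content, for
  testing AST (adeno-to-squamous transdifferentiation) scores.

The latent model per time point ``t`` and replicate is

    x_g = sqrt(rho_x) * F + m_g(t) * M + e_g

with a common background factor ``F`` shared by all genes, a module factor
``M`` shared by module genes, and independent noise ``e_g``; variances are
chosen so that within-module correlation is ``rho_base`` away from
``t_star`` and ``rho_peak`` at ``t_star``, where additionally the module's
loading on ``F`` is zeroed (cross-correlation drop) and its latent standard
deviation is multiplied by ``sd_inflation``.  Latent values are log2-scale
deviations around per-gene base means and are emitted as negative-binomial
counts with dispersion ``nb_dispersion``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CountMatrix, ExpressionMatrix, TimeCourseDesign

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "CohortTruth",
    "generate_timecourse",
    "generate_adsc_cohort",
    "generate_cohort_counts",
]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-transition generator.

    Defaults mirror the study design: 7 serial time points (weeks 0-10
    post induction), a mid-course tipping point at 7 weeks, and a 30-gene
    DNB module inside a 600-gene background.
    """

    n_genes: int = 600
    module_size: int = 30
    time_points_weeks: tuple[float, ...] = (0, 4, 6, 7, 8, 9, 10)
    replicates_per_timepoint: int = 6
    t_star_weeks: float = 7
    rho_base: float = 0.2
    rho_peak: float = 0.85
    sd_inflation: float = 3.0
    n_adc_markers: int = 20
    n_scc_markers: int = 20
    switch_steepness: float = 0.5  # weeks; sigmoid scale of the marker switch
    switch_magnitude: float = 3.0  # log2 units swung by each marker
    module_switch_magnitude: float = 3.0  # coherent log2 shift of module genes over the switch
    nb_dispersion: float = 0.1
    mean_log_expression: tuple[float, float] = (5.0, 10.0)  # log2 count range
    latent_sd: float = 1.0  # log2-scale SD of the latent model
    rho_cross: float = 0.1  # module/background shared-factor correlation
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.rho_base <= self.rho_peak < 1:
            raise ConfigError("need 0 <= rho_base <= rho_peak < 1")
        if self.sd_inflation < 1:
            raise ConfigError("sd_inflation must be >= 1")
        if self.t_star_weeks not in self.time_points_weeks:
            raise ConfigError("t_star_weeks must be one of time_points_weeks")
        if self.module_size + self.n_adc_markers + self.n_scc_markers > self.n_genes:
            raise ConfigError("module plus marker genes exceed n_genes")
        if not 0 <= self.rho_cross <= self.rho_base:
            raise ConfigError("need 0 <= rho_cross <= rho_base")
        if self.module_size < 2 or self.n_genes < 10:
            raise ConfigError("module_size >= 2 and n_genes >= 10 required")
        if self.replicates_per_timepoint < 1:
            raise ConfigError("replicates_per_timepoint must be >= 1")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if len(set(self.time_points_weeks)) != len(self.time_points_weeks):
            raise ConfigError("time points must be unique")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated time course, for recovery tests."""

    module_gene_ids: list[str]
    adc_marker_ids: list[str]
    scc_marker_ids: list[str]
    t_star_index: int
    t_star_weeks: float
    latent_correlation: list[float] = field(default_factory=list)
    latent_sd: list[float] = field(default_factory=list)


@dataclass
class CohortTruth:
    """Ground truth of a generated AdSCC cohort."""

    fractions: np.ndarray  # squamous-program fraction per sample, in [0,1]
    adc_marker_ids: list[str]
    scc_marker_ids: list[str]
    wnt_like_ids: list[str]


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw via gamma-Poisson mixture; dispersion 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _gene_names(cfg: SyntheticConfig) -> tuple[list[str], slice, slice, slice]:
    """Deterministic gene naming: module, ADC markers, SCC markers, background."""
    m, a, s = cfg.module_size, cfg.n_adc_markers, cfg.n_scc_markers
    names = (
        [f"MOD{i:04d}" for i in range(m)]
        + [f"ADC{i:04d}" for i in range(a)]
        + [f"SCC{i:04d}" for i in range(s)]
        + [f"BG{i:05d}" for i in range(cfg.n_genes - m - a - s)]
    )
    return names, slice(0, m), slice(m, m + a), slice(m + a, m + a + s)


def latent_module_draws(
    cfg: SyntheticConfig, at_tipping: bool, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw latent log2 deviations for the module genes only (draws x genes).

    Exposed so tests can Monte-Carlo the latent model independently of the
    count emission.
    """
    m = cfg.module_size
    sigma = cfg.latent_sd
    if at_tipping:
        load_f, load_m = 0.0, np.sqrt(cfg.rho_peak)
        noise = np.sqrt(1.0 - cfg.rho_peak)
        scale = sigma * cfg.sd_inflation
    else:
        load_f = np.sqrt(cfg.rho_cross)
        load_m = np.sqrt(cfg.rho_base - cfg.rho_cross)
        noise = np.sqrt(1.0 - cfg.rho_base)
        scale = sigma
    F = rng.standard_normal((n_draws, 1))
    M = rng.standard_normal((n_draws, 1))
    E = rng.standard_normal((n_draws, m))
    return scale * (load_f * F + load_m * M + noise * E)


def generate_timecourse(
    cfg: SyntheticConfig,
) -> tuple[CountMatrix, TimeCourseDesign, SyntheticTruth]:
    """Generate a replicated multi-timepoint count matrix with planted structure."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])

    names, mod_sl, adc_sl, scc_sl = _gene_names(cfg)
    n_bg = cfg.n_genes - cfg.module_size - cfg.n_adc_markers - cfg.n_scc_markers
    lo, hi = cfg.mean_log_expression
    base_log = rng.uniform(lo, hi, size=cfg.n_genes)

    times = list(cfg.time_points_weeks)
    t_star_index = times.index(cfg.t_star_weeks)
    sigma = cfg.latent_sd
    reps = cfg.replicates_per_timepoint

    sample_ids: list[str] = []
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    latent_corr: list[float] = []
    latent_sd_profile: list[float] = []

    for ti, t in enumerate(times):
        at_star = ti == t_star_index
        latent_corr.append(cfg.rho_peak if at_star else cfg.rho_base)
        latent_sd_profile.append(sigma * (cfg.sd_inflation if at_star else 1.0))
        # sigmoid switch of the lineage markers, centered at the tipping point
        s_t = float(_sigmoid((t - cfg.t_star_weeks) / cfg.switch_steepness))
        for r in range(reps):
            F = rng.standard_normal()
            M = rng.standard_normal()
            x = np.empty(cfg.n_genes)
            # module genes: equicorrelated latent block
            if at_star:
                e = rng.standard_normal(cfg.module_size)
                x[mod_sl] = (sigma * cfg.sd_inflation) * (
                    np.sqrt(cfg.rho_peak) * M + np.sqrt(1 - cfg.rho_peak) * e
                )
            else:
                e = rng.standard_normal(cfg.module_size)
                x[mod_sl] = sigma * (
                    np.sqrt(cfg.rho_cross) * F
                    + np.sqrt(cfg.rho_base - cfg.rho_cross) * M
                    + np.sqrt(1 - cfg.rho_base) * e
                )
            # module genes are lineage-differential (drawn from the ADC/SCC
            # differential subspace): coherent down-switch across the transition
            x[mod_sl] += cfg.module_switch_magnitude * (1 - s_t)
            # markers: independent noise around the switching mean
            x[adc_sl] = cfg.switch_magnitude * (1 - s_t) + sigma * rng.standard_normal(
                cfg.n_adc_markers
            )
            x[scc_sl] = cfg.switch_magnitude * s_t + sigma * rng.standard_normal(
                cfg.n_scc_markers
            )
            # background genes share the common factor F
            e_bg = rng.standard_normal(n_bg)
            x[cfg.module_size + cfg.n_adc_markers + cfg.n_scc_markers :] = sigma * (
                np.sqrt(cfg.rho_cross) * F + np.sqrt(1 - cfg.rho_cross) * e_bg
            )
            mean = 2.0 ** (base_log + x)
            cols.append(_nb_counts(rng, mean, cfg.nb_dispersion))
            sid = f"T{t:g}W_r{r + 1}"
            sample_ids.append(sid)
            phenotype = "ADC" if t < cfg.t_star_weeks else ("SCC" if t > cfg.t_star_weeks else "ADC")
            if t == 0:
                phenotype = "NL"
            rows.append(
                {"sample_id": sid, "time_weeks": t, "phenotype": phenotype, "replicate": r + 1}
            )

    counts = CountMatrix(
        gene_ids=names, sample_ids=sample_ids, counts=np.column_stack(cols)
    )
    design = TimeCourseDesign(table=pd.DataFrame(rows))
    truth = SyntheticTruth(
        module_gene_ids=names[mod_sl],
        adc_marker_ids=names[adc_sl],
        scc_marker_ids=names[scc_sl],
        t_star_index=t_star_index,
        t_star_weeks=cfg.t_star_weeks,
        latent_correlation=latent_corr,
        latent_sd=latent_sd_profile,
    )
    return counts, design, truth


def generate_adsc_cohort(
    n_samples: int,
    mixture_fractions: np.ndarray | list[float],
    cfg: SyntheticConfig | None = None,
    noise_sd: float = 0.5,
    n_wnt_like: int = 15,
    wnt_decay: float = 2.0,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Generate a tumor-cohort expression matrix mixing ADC and SCC programs.

    Each sample's marker expression is the convex mixture
    ``(1 - f) * ADC_profile + f * SCC_profile`` plus Gaussian noise, where
    ``f`` is its squamous-program fraction.  A planted "Wnt-like" gene set
    decays linearly with ``f`` by ``wnt_decay`` log2 units, mimicking Wnt
    signaling being switched off as tumors become squamous.
    """
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    fractions = np.asarray(mixture_fractions, dtype=float)
    if fractions.shape != (n_samples,):
        raise ConfigError("need one mixture fraction per sample")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ConfigError("mixture fractions must lie in [0, 1]")
    if n_wnt_like < 0 or cfg.module_size + cfg.n_adc_markers + cfg.n_scc_markers + n_wnt_like > cfg.n_genes:
        raise ConfigError("n_wnt_like does not fit in n_genes")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]).spawn(1)[0])
    names, mod_sl, adc_sl, scc_sl = _gene_names(cfg)
    n_markers_end = cfg.module_size + cfg.n_adc_markers + cfg.n_scc_markers
    wnt_ids = [f"WNT{i:03d}" for i in range(n_wnt_like)]
    # replace the first background genes with the Wnt-like set
    names = names[:n_markers_end] + wnt_ids + names[n_markers_end + n_wnt_like :]
    wnt_sl = slice(n_markers_end, n_markers_end + n_wnt_like)

    lo, hi = cfg.mean_log_expression
    base = rng.uniform(lo, hi, size=cfg.n_genes)
    values = base[:, None] + noise_sd * rng.standard_normal((cfg.n_genes, n_samples))
    # ADC program high at f=0, SCC program high at f=1; module genes belong
    # to the lineage-differential program (down in SCC), as in the time course
    values[adc_sl] += cfg.switch_magnitude * (1 - fractions)[None, :]
    values[scc_sl] += cfg.switch_magnitude * fractions[None, :]
    values[mod_sl] += cfg.module_switch_magnitude * (1 - fractions)[None, :]
    values[wnt_sl] -= wnt_decay * fractions[None, :]

    expr = ExpressionMatrix(
        gene_ids=names,
        sample_ids=[f"TUMOR{i + 1:03d}" for i in range(n_samples)],
        values=values,
    )
    truth = CohortTruth(
        fractions=fractions,
        adc_marker_ids=names[adc_sl],
        scc_marker_ids=names[scc_sl],
        wnt_like_ids=wnt_ids,
    )
    return expr, truth


def generate_cohort_counts(groups: list[tuple[str, int, int]]):
    """Validate and wrap (group, n_total, n_with_scc) rows as a CohortTable."""
    from .cohort import CohortTable  # local import to avoid a cycle

    return CohortTable.from_rows(groups)
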
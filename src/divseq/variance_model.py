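"""Variance decomposition and replicate-based over-dispersion calibration.

A count measurement carries three independent variance components: Poisson
sampling noise (variance equal to the mean count), technical imprecision from
library preparation and sequencing, and the gene's environmental response.
The latter two are "non-Poisson" and are expressed as a *relative* SD
(sigma_nP) multiplying the mean, so the total variance of a count with
expectation mu composes as

    sigma_total^2(mu) = mu + (sigma_nP * mu)^2

which is the single composition rule used everywhere in this package.

Per gene, the relative non-Poisson SD is isolated from a replicate pair:
with R the mean replicate count and sigma_reps^2 the sample variance,
sigma_nP^2 = sigma_reps^2 - R (clamped at zero) and sigma_m =
sqrt(sigma_nP^2) / R. With two replicates this is a noisy estimate, so
gene-specific SDs are pooled across species (weighted by read count),
floored by the technical resolution sigma_t, and rescaled by each species'
uniform over-dispersion U relative to the across-species mean U.

U itself is calibrated from replicates: since the null is true for every
gene in a self-comparison, U is the smallest value at which the fraction of
replicate genes called DE at level alpha does not exceed alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountTable
from .normalization import distribution_means_vector, median_ratio_slope

DEFAULT_GRID_STEP = 0.001
DEFAULT_U_MAX = 2.0
DEFAULT_CALIBRATION_ALPHA = 0.05
MIN_CALIBRATION_READS = 10
MIN_POOL_READS = 30


class CalibrationError(ValueError):
    """Replicate pair unusable for over-dispersion calibration."""


def total_variance(mu: np.ndarray | float, sigma_np: np.ndarray | float) -> np.ndarray | float:
    """Poisson plus relative non-Poisson variance at mean ``mu``."""
    return mu + (sigma_np * mu) ** 2


def replicate_nonpoisson_sd(rep_counts: Sequence[float]) -> tuple[float, float]:
    """Gene-specific relative non-Poisson SD and its read-count weight.

    Returns ``(sigma_m, R)`` where R is the mean replicate count. The
    non-Poisson variance (sample variance minus R) is clamped at zero:
    with few replicates many genes repeat exactly by chance.
    """
    counts = np.asarray(rep_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 replicate counts")
    r = float(counts.mean())
    if r == 0.0:
        return 0.0, 0.0
    var_reps = float(counts.var(ddof=1))
    sigma_np_sq = max(0.0, var_reps - r)
    return float(np.sqrt(sigma_np_sq)) / r, r


def apply_technical_floor(sigma_m: float, sigma_t: float) -> float:
    """Floor a measured relative SD at the technology's resolution."""
    if sigma_m < 0 or sigma_t < 0:
        raise ValueError("relative SDs must be non-negative")
    return max(sigma_m, sigma_t)


def species_rescale(sigma: float, u_species: float, u_all: Iterable[float]) -> float:
    """Scale a pooled gene SD by the species' U relative to the mean U."""
    u_all = list(u_all)
    if u_species <= 0 or any(u <= 0 for u in u_all):
        raise ValueError("U values must be positive")
    return sigma * u_species / (sum(u_all) / len(u_all))


@dataclass
class OverdispersionCalibration:
    """Result of the minimal-U grid search on one replicate pair."""

    U: float
    alpha: float
    n_genes_calibrated: int
    n_de_at_U: int
    sigma_t: float | None = None
    underdispersed: bool = False  # U=0 already met the target
    at_grid_max: bool = False


def _count_de(
    c: np.ndarray, t: np.ndarray, mu_c: np.ndarray, mu_t: np.ndarray, u: float, crit: float
) -> int:
    """Genes whose chi-square statistic at uniform sigma_nP = u exceeds crit."""
    with np.errstate(invalid="ignore", divide="ignore"):
        x2 = (c - mu_c) ** 2 / total_variance(mu_c, u) + (t - mu_t) ** 2 / total_variance(mu_t, u)
    x2 = np.where((mu_c == 0) & (mu_t == 0), 0.0, x2)
    return int((x2 > crit).sum())


def calibrate_U(
    control: CountTable,
    test: CountTable,
    alpha: float = DEFAULT_CALIBRATION_ALPHA,
    min_mean_reads: int = MIN_CALIBRATION_READS,
    grid_step: float = DEFAULT_GRID_STEP,
    u_max: float = DEFAULT_U_MAX,
    genes: Iterable[str] | None = None,
) -> OverdispersionCalibration:
    """Calibrate the uniform over-dispersion U from a replicate self-pair.

    The two samples are compared with the chi-square test using a uniform
    relative SD; U is the smallest grid value at which the number of genes
    with p < alpha is at most alpha times the number of eligible genes
    (mean count >= ``min_mean_reads``). Since every gene's statistic is
    non-increasing in U, the minimal U is found by bisection on the grid.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    common = control.counts.index.intersection(test.counts.index)
    if genes is not None:
        common = common.intersection(pd.Index(genes))
    c_all = control.counts.loc[common].to_numpy(dtype=float)
    t_all = test.counts.loc[common].to_numpy(dtype=float)
    eligible = (c_all + t_all) / 2.0 >= min_mean_reads
    c, t = c_all[eligible], t_all[eligible]
    n = int(c.size)
    if n == 0:
        raise CalibrationError("no genes pass the mean-count filter")
    m = median_ratio_slope(
        pd.Series(c, index=range(n)), pd.Series(t, index=range(n))
    )
    mu_c, mu_t = distribution_means_vector(c, t, m)
    crit = float(stats.chi2.isf(alpha, df=1))
    target = alpha * n

    if _count_de(c, t, mu_c, mu_t, 0.0, crit) <= target:
        return OverdispersionCalibration(
            U=0.0, alpha=alpha, n_genes_calibrated=n,
            n_de_at_U=_count_de(c, t, mu_c, mu_t, 0.0, crit), underdispersed=True,
        )

    n_grid = int(round(u_max / grid_step))
    if _count_de(c, t, mu_c, mu_t, u_max, crit) > target:
        return OverdispersionCalibration(
            U=u_max, alpha=alpha, n_genes_calibrated=n,
            n_de_at_U=_count_de(c, t, mu_c, mu_t, u_max, crit), at_grid_max=True,
        )
    # bisection for the smallest grid index meeting the target
    lo, hi = 0, n_grid  # count(lo) > target, count(hi) <= target
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _count_de(c, t, mu_c, mu_t, mid * grid_step, crit) <= target:
            hi = mid
        else:
            lo = mid
    u = hi * grid_step
    return OverdispersionCalibration(
        U=u, alpha=alpha, n_genes_calibrated=n,
        n_de_at_U=_count_de(c, t, mu_c, mu_t, u, crit),
    )


@dataclass
class GeneVariance:
    """Cross-species pooled relative non-Poisson SD for one gene."""

    gene_id: str
    sigma_m_per_species: dict[str, tuple[float, float]]  # species -> (sigma_m, R)
    sigma_np_pooled: float
    fallback_used: bool


def pooled_gene_variance(
    gene_id: str,
    per_species_estimates: Mapping[str, tuple[float, float]],
    per_species_u: Mapping[str, float],
    sigma_t: float,
    min_pool_reads: int = MIN_POOL_READS,
) -> GeneVariance:
    """Pool one gene's per-species (sigma_m, R) estimates.

    Estimates with R below ``min_pool_reads`` are discarded as Poisson-
    dominated; survivors are averaged weighted by R and floored by sigma_t.
    If nothing survives the gene falls back to the species-level U
    (resolved per species at test time), flagged ``fallback_used``.
    """
    kept = {sp: (s, r) for sp, (s, r) in per_species_estimates.items() if r >= min_pool_reads}
    if not kept:
        return GeneVariance(gene_id, dict(per_species_estimates), float("nan"), True)
    weights = np.array([r for _, r in kept.values()])
    sigmas = np.array([s for s, _ in kept.values()])
    pooled = float((weights * sigmas).sum() / weights.sum())
    return GeneVariance(
        gene_id, dict(per_species_estimates), apply_technical_floor(pooled, sigma_t), False
    )


@dataclass
class VarianceModel:
    """Everything the test statistic needs to know about variance."""

    u_by_species: dict[str, float]
    sigma_t: float
    gene_sigma: pd.Series  # pooled+floored sigma per gene; NaN = fallback
    fallback_genes: set[str] = field(default_factory=set)

    @property
    def mean_u(self) -> float:
        return float(np.mean(list(self.u_by_species.values())))

    def sigma_for(self, gene: str, species: str) -> float:
        """Per-gene relative SD to use in a test involving ``species``."""
        u = self.u_by_species[species]
        sigma = self.gene_sigma.get(gene, float("nan"))
        if np.isnan(sigma):
            return u
        return species_rescale(sigma, u, self.u_by_species.values())

    def sigma_vector(self, genes: pd.Index | Sequence[str], species: str) -> np.ndarray:
        u = self.u_by_species[species]
        sigma = self.gene_sigma.reindex(pd.Index(genes)).to_numpy(dtype=float)
        scaled = sigma * u / self.mean_u
        return np.where(np.isnan(scaled), u, scaled)


def build_variance_model(
    replicate_pairs: Mapping[str, tuple[CountTable, CountTable]],
    sigma_t: float,
    alpha: float = DEFAULT_CALIBRATION_ALPHA,
    genes: Iterable[str] | None = None,
    min_mean_reads: int = MIN_CALIBRATION_READS,
    min_pool_reads: int = MIN_POOL_READS,
) -> VarianceModel:
    """Calibrate U per species and pool per-gene replicate variances.

    ``replicate_pairs`` maps each species to its biological replicate pair.
    ``sigma_t`` is the technical floor — itself a U calibrated on a technical
    replicate pair (use :func:`calibrate_U` on one, restricted to coding
    genes) or taken from a previous characterization of the platform.
    """
    u_by_species: dict[str, float] = {}
    per_gene: dict[str, dict[str, tuple[float, float]]] = {}
    for species, (rep1, rep2) in replicate_pairs.items():
        cal = calibrate_U(rep1, rep2, alpha=alpha, min_mean_reads=min_mean_reads, genes=genes)
        u_by_species[species] = max(cal.U, 1e-6)  # keep rescaling ratios defined
        common = rep1.counts.index.intersection(rep2.counts.index)
        if genes is not None:
            common = common.intersection(pd.Index(genes))
        c1 = rep1.counts.loc[common].to_numpy(dtype=float)
        c2 = rep2.counts.loc[common].to_numpy(dtype=float)
        r = (c1 + c2) / 2.0
        var_reps = (c1 - r) ** 2 + (c2 - r) ** 2  # ddof=1 sample variance, n=2
        sigma_np_sq = np.maximum(0.0, var_reps - r)
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma_m = np.where(r > 0, np.sqrt(sigma_np_sq) / np.maximum(r, 1e-300), 0.0)
        for gene, s, w in zip(common, sigma_m, r):
            per_gene.setdefault(gene, {})[species] = (float(s), float(w))

    gene_sigma = {}
    fallback: set[str] = set()
    for gene, estimates in per_gene.items():
        gv = pooled_gene_variance(gene, estimates, u_by_species, sigma_t, min_pool_reads)
        gene_sigma[gene] = gv.sigma_np_pooled
        if gv.fallback_used:
            fallback.add(gene)
    return VarianceModel(
        u_by_species=u_by_species,
        sigma_t=sigma_t,
        gene_sigma=pd.Series(gene_sigma, dtype=float),
        fallback_genes=fallback,
    )
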
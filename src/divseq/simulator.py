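"""Synthetic count datasets with the statistical structure the test assumes,
plus the evaluation harness (false-positive rate, power, CI coverage).

Generative model, per gene g and sample s:

    mu_g        ~ LogNormal(log_mean, log_sd)        expected count
    sigma_g     = U               (uniform model) or
                ~ LogNormal centred on U             (per-gene model)
    e_{g,s}     ~ LogNormal with mean 1 and CV sigma_g   latent expression
    count_{g,s} ~ Poisson(mu_g * e_{g,s} * depth_s * 2^shift_g)

The multiplicative latent factor reflects how expression varies — both
environmental response and evolutionary change act on transcription rates,
i.e. multiplicatively. With de_fraction = 0 every gene satisfies the null
exactly. Injected shifts are applied to one species and are either a fixed
log2 fold change, a draw from a normal on the log2 scale, or a Cohen's D —
a multiple of the null SD of the log2 fold change at the gene's own depth,
so "effect size 2" means two null SDs regardless of expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CountTable, Sample
from .de_test import LN2, fold_change_ci
from .normalization import median_ratio_slope

DEFAULT_SPECIES = ["cerevisiae", "paradoxus", "mikatae", "bayanus"]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the regime of a deeply sequenced yeast experiment:
    10,000 genes with log-normal mean counts spanning roughly 10 to 10,000
    reads (so >95% of genes clear the 10-read floor), relative non-Poisson
    over-dispersion 0.16 (the technical resolution of the platform), two
    same-day batches per species.
    """

    n_genes: int = 10_000
    log_mean: float = 5.0
    log_sd: float = 1.5
    overdispersion_model: str = "uniform"  # "uniform" | "lognormal"
    overdispersion_u: float = 0.16
    overdispersion_log_sd: float = 0.5  # spread of per-gene sigma (lognormal model)
    de_fraction: float = 0.0
    effect_model: str = "fixed"  # "fixed" | "normal" | "cohens_d"
    effect_size: float = 1.0  # log2 FC, SD of log2 FC, or Cohen's D
    n_species: int = 2
    n_replicates: int = 2
    species_names: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SPECIES))
    depth_factors: Mapping[str, float] | None = None  # per sample_id
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.overdispersion_model not in ("uniform", "lognormal"):
            raise ValueError(f"unknown overdispersion model {self.overdispersion_model!r}")
        if self.effect_model not in ("fixed", "normal", "cohens_d"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if self.overdispersion_u < 0 or self.log_sd <= 0:
            raise ValueError("invalid distribution parameters")
        if self.n_species > len(self.species_names):
            raise ValueError("not enough species names")


def _lognormal_unit_mean(rng: np.random.Generator, cv: np.ndarray, size: int) -> np.ndarray:
    """Draws with mean 1 and relative SD ``cv`` (elementwise)."""
    sd_ln = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sd_ln**2, sigma=sd_ln, size=size)


def null_fc_sd(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Approximate SD of the log2 fold change between two null samples of a
    gene with mean ``mu`` and relative non-Poisson SD ``sigma``."""
    return np.sqrt(2.0 * (1.0 / mu + sigma**2)) / LN2


def simulate_dataset(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, CountTable], pd.DataFrame]:
    """Generate count tables and the ground-truth table.

    Returns ``(tables, truth)`` where ``tables`` maps sample_id to a
    :class:`CountTable` (sample ids look like ``cerevisiae_r1`` with batch
    ``day1``) and ``truth`` has one row per gene: its expected count ``mu``,
    relative non-Poisson SD ``sigma_np``, ``is_de``, and ``true_log2_fc``
    (the shift applied to the second species; 0 elsewhere). DE shifts are
    only injected when at least two species are simulated.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    mu = rng.lognormal(mean=spec.log_mean, sigma=spec.log_sd, size=n)
    if spec.overdispersion_model == "uniform":
        sigma = np.full(n, spec.overdispersion_u)
    else:
        sigma = rng.lognormal(
            mean=np.log(max(spec.overdispersion_u, 1e-12)),
            sigma=spec.overdispersion_log_sd,
            size=n,
        )

    shift = np.zeros(n)
    is_de = np.zeros(n, dtype=bool)
    if spec.de_fraction > 0 and spec.n_species >= 2:
        n_de = int(round(spec.de_fraction * n))
        chosen = rng.choice(n, size=n_de, replace=False)
        is_de[chosen] = True
        signs = rng.choice([-1.0, 1.0], size=n_de)
        if spec.effect_model == "fixed":
            shift[chosen] = signs * spec.effect_size
        elif spec.effect_model == "normal":
            shift[chosen] = rng.normal(0.0, spec.effect_size, size=n_de)
        else:  # cohens_d: effect in units of the null log2-FC spread
            shift[chosen] = signs * spec.effect_size * null_fc_sd(mu[chosen], sigma[chosen])

    tables: dict[str, CountTable] = {}
    for sp_idx in range(spec.n_species):
        species = spec.species_names[sp_idx]
        species_mu = mu * np.exp2(shift) if sp_idx == 1 else mu
        for rep in range(1, spec.n_replicates + 1):
            sample_id = f"{species}_r{rep}"
            depth = 1.0
            if spec.depth_factors is not None:
                depth = float(spec.depth_factors.get(sample_id, 1.0))
            e = _lognormal_unit_mean(rng, sigma, n)
            counts = rng.poisson(species_mu * e * depth)
            sample = Sample(
                sample_id=sample_id,
                species=species,
                replicate_index=rep,
                batch=f"day{rep}",
            )
            tables[sample_id] = CountTable(sample, pd.Series(counts, index=genes, dtype="int64"))

    truth = pd.DataFrame(
        {"mu": mu, "sigma_np": sigma, "is_de": is_de, "true_log2_fc": shift}, index=genes
    )
    return tables, truth


def simulate_replicate_pair(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[CountTable, CountTable, pd.DataFrame]:
    """Two replicates of a single species — the calibration fixture."""
    one = SimulationSpec(**{**spec.__dict__, "n_species": 1, "n_replicates": 2})
    tables, truth = simulate_dataset(one, rng=rng)
    (r1, r2) = (tables[f"{one.species_names[0]}_r1"], tables[f"{one.species_names[0]}_r2"])
    return r1, r2, truth


def evaluate_fpr_power(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    alpha: float | None = None,
    n_strata: int = 4,
) -> tuple[float, float, pd.DataFrame]:
    """False-positive rate, power, and an FPR breakdown by variance stratum.

    ``results`` is a DE table with gene_id and is_de (or p_combined when
    ``alpha`` is given, in which case calls are recomputed at that level).
    The breakdown stratifies the null genes by quantile of their true
    relative SD — a caller biased against high-variance genes shows a
    rising profile.
    """
    merged = results.set_index("gene_id")
    merged = merged.loc[merged.index.intersection(truth.index)]
    calls = (merged["p_combined"] < alpha) if alpha is not None else merged["is_de"].astype(bool)
    truth_de = truth.loc[merged.index, "is_de"].astype(bool)
    n_null = int((~truth_de).sum())
    n_de = int(truth_de.sum())
    fpr = float((calls & ~truth_de).sum() / n_null) if n_null else float("nan")
    power = float((calls & truth_de).sum() / n_de) if n_de else float("nan")

    sigma = truth.loc[merged.index, "sigma_np"]
    null_idx = merged.index[~truth_de]
    if len(null_idx) >= n_strata and sigma.loc[null_idx].nunique() > 1:
        strata = pd.qcut(sigma.loc[null_idx], q=n_strata, duplicates="drop")
    else:
        strata = pd.Series("all", index=null_idx)
    breakdown = (
        pd.DataFrame({"stratum": strata, "false_call": calls.loc[null_idx]})
        .groupby("stratum", observed=True)["false_call"]
        .agg(fpr="mean", n="size")
        .reset_index()
    )
    return fpr, power, breakdown


def evaluate_ci_coverage(
    control: CountTable,
    test: CountTable,
    truth: pd.DataFrame,
    sigma: pd.Series | np.ndarray | None = None,
    z: float = 2.0,
) -> tuple[float, int, int]:
    """Fraction of genes whose +/- z*sigma log2-FC interval contains the
    true fold change.

    Counts are put on a common scale with the median-ratio slope, split
    symmetrically between the two samples (control * sqrt(m), test /
    sqrt(m)) so neither side absorbs the whole rescaling. ``sigma`` defaults
    to the generative relative SD from ``truth``. Returns (coverage,
    n_defined, n_na); genes with a zero count have no defined interval and
    are excluded but counted in ``n_na``.
    """
    genes = truth.index
    c = control.counts.reindex(genes).to_numpy(dtype=float)
    t = test.counts.reindex(genes).to_numpy(dtype=float)
    m = median_ratio_slope(control.counts, test.counts, genes=genes)
    c_n = c * np.sqrt(m)
    t_n = t / np.sqrt(m)
    if sigma is None:
        sigma = truth["sigma_np"]
    sigma = np.asarray(sigma, dtype=float)
    true_fc = truth["true_log2_fc"].to_numpy(dtype=float)

    defined = (c_n > 0) & (t_n > 0)
    covered = 0
    for i in np.flatnonzero(defined):
        fc, sd = fold_change_ci(c_n[i], t_n[i], sigma[i], sigma[i])
        if fc - z * sd <= true_fc[i] <= fc + z * sd:
            covered += 1
    n_defined = int(defined.sum())
    coverage = covered / n_defined if n_defined else float("nan")
    return coverage, n_defined, int((~defined).sum())
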
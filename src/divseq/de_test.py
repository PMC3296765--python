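"""Over-dispersed chi-square differential-expression test.

For a gene with counts C_g (control) and T_g (test), the null hypothesis is
that both were drawn from a common expression level. The null means
(mu_C, mu_T) come from the midpoint projection onto the normalization slope;
the statistic is

    X^2 = (C_g - mu_C)^2 / [mu_C + (sigma_C mu_C)^2]
        + (T_g - mu_T)^2 / [mu_T + (sigma_T mu_T)^2]

with sigma_* the calibrated relative non-Poisson SDs. Although two terms are
summed, the common mean was estimated from the same two observations, so one
degree of freedom is lost and p-values come from chi-square with 1 DF.

Batch effects are neutralized by testing only same-day sample pairs
(Rep1 vs Rep1, Rep2 vs Rep2) and combining the per-batch p-values with
Fisher's method. Fold-change confidence intervals propagate the count
uncertainties onto the log2 scale (+/- 2 SD ~ 95%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountTable
from .normalization import (
    common_reference_total,
    distribution_means,
    distribution_means_vector,
    median_ratio_slope,
)
from .variance_model import VarianceModel, total_variance

LN2 = math.log(2.0)
DEFAULT_ALPHA = 0.01
MIN_TEST_READS = 10


def chi2_statistic(
    c_g: float,
    t_g: float,
    m: float,
    sigma_np_c: float,
    sigma_np_t: float,
) -> float:
    """Two-by-one over-dispersed chi-square statistic for one gene."""
    if c_g < 0 or t_g < 0 or sigma_np_c < 0 or sigma_np_t < 0:
        raise ValueError("counts and relative SDs must be non-negative")
    mu_c, mu_t = distribution_means(c_g, t_g, m)
    if mu_c == 0 and mu_t == 0:
        return 0.0
    return (c_g - mu_c) ** 2 / total_variance(mu_c, sigma_np_c) + (
        t_g - mu_t
    ) ** 2 / total_variance(mu_t, sigma_np_t)


def chi2_statistic_vector(
    c: np.ndarray,
    t: np.ndarray,
    m: float,
    sigma_c: np.ndarray | float,
    sigma_t_: np.ndarray | float,
) -> np.ndarray:
    """Vectorized :func:`chi2_statistic` over aligned count arrays."""
    mu_c, mu_t = distribution_means_vector(c, t, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        x2 = (c - mu_c) ** 2 / total_variance(mu_c, sigma_c) + (
            t - mu_t
        ) ** 2 / total_variance(mu_t, sigma_t_)
    return np.where((mu_c == 0) & (mu_t == 0), 0.0, x2)


def p_value(chi2: float | np.ndarray, df: int = 1) -> float | np.ndarray:
    """Upper-tail chi-square probability (1 DF by default; see module doc)."""
    return stats.chi2.sf(chi2, df=df)


def combine_batches(p_values: Sequence[float]) -> float:
    """Fisher's combined probability over independent same-batch tests."""
    ps = np.asarray(p_values, dtype=float)
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(x, df=2 * len(ps)))


def fold_change_ci(
    c_gn: float,
    t_gn: float,
    sigma_np_c: float,
    sigma_np_t: float,
) -> tuple[float, float]:
    """log2 fold change and its propagated SD from size-normalized counts.

    Each count's variance composes Poisson and relative non-Poisson parts;
    dividing its SD by (count * ln 2) converts to log2 units, and the two
    samples' contributions add in quadrature. Returns (log2_fc, sigma_fc);
    both are NaN when either count is zero (the ratio is undefined).
    """
    if c_gn < 0 or t_gn < 0:
        raise ValueError("normalized counts must be non-negative")
    if c_gn == 0 or t_gn == 0:
        return float("nan"), float("nan")
    var_t = total_variance(t_gn, sigma_np_t)
    var_c = total_variance(c_gn, sigma_np_c)
    sigma_fc = math.sqrt(
        var_t / (t_gn * LN2) ** 2 + var_c / (c_gn * LN2) ** 2
    )
    return math.log2(t_gn / c_gn), sigma_fc


@dataclass
class BatchPair:
    """One same-day control/test sample pair."""

    batch: str
    control: CountTable
    test: CountTable


def batch_pairs(
    samples: Iterable[CountTable], species_control: str, species_test: str
) -> list[BatchPair]:
    """Match control- and test-species samples by batch label."""
    by_key: dict[tuple[str, str], CountTable] = {}
    for tbl in samples:
        by_key[(tbl.sample.species, tbl.sample.batch)] = tbl
    pairs = []
    for (species, batch), tbl in sorted(by_key.items()):
        if species != species_control:
            continue
        other = by_key.get((species_test, batch))
        if other is not None:
            pairs.append(BatchPair(batch=batch, control=tbl, test=other))
    return pairs


def call_de(
    samples: Iterable[CountTable],
    comparison: tuple[str, str],
    variance: VarianceModel,
    genes: Iterable[str],
    ortholog_of: Mapping[str, Mapping[str, str]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_reads: int = MIN_TEST_READS,
) -> pd.DataFrame:
    """Run the full batch-paired test for one species comparison.

    ``genes`` are reference-species IDs (the measurable 1:1 orthologs of the
    comparison); ``ortholog_of[species][ref_gene]`` translates them into each
    species' own count-table IDs (identity when omitted). The fold change and
    its CI are taken from the first batch's pair. Genes whose mean count in
    some batch falls below ``min_reads`` are still tested but flagged
    ``low_count``.
    """
    species_c, species_t = comparison
    pairs = batch_pairs(samples, species_c, species_t)
    if not pairs:
        raise ValueError(f"no batch-matched sample pairs for {species_c} vs {species_t}")
    gene_index = pd.Index(genes)

    def ids_for(species: str) -> pd.Index:
        if ortholog_of is None or species not in ortholog_of:
            return gene_index
        return pd.Index([ortholog_of[species][g] for g in gene_index])

    ids_c, ids_t = ids_for(species_c), ids_for(species_t)
    sigma_c = variance.sigma_vector(gene_index, species_c)
    sigma_t_ = variance.sigma_vector(gene_index, species_t)

    chi2_cols, p_cols, low = [], [], np.zeros(len(gene_index), dtype=bool)
    first_c = first_t = None
    for pair in pairs:
        c = pair.control.counts.reindex(ids_c).to_numpy(dtype=float)
        t = pair.test.counts.reindex(ids_t).to_numpy(dtype=float)
        if np.isnan(c).any() or np.isnan(t).any():
            missing = gene_index[np.isnan(c) | np.isnan(t)][0]
            raise ValueError(f"gene {missing!r} missing from batch {pair.batch} counts")
        m = median_ratio_slope(
            pd.Series(c, index=gene_index), pd.Series(t, index=gene_index)
        )
        x2 = chi2_statistic_vector(c, t, m, sigma_c, sigma_t_)
        chi2_cols.append(x2)
        p_cols.append(stats.chi2.sf(x2, df=1))
        low |= (c + t) / 2.0 < min_reads
        if first_c is None:
            first_c, first_t = c, t

    fisher_x = -2.0 * np.log(np.clip(np.column_stack(p_cols), 1e-300, 1.0)).sum(axis=1)
    p_combined = stats.chi2.sf(fisher_x, df=2 * len(pairs))

    ref_total = common_reference_total(int(first_c.sum()), int(first_t.sum()))
    c_n = first_c * ref_total / first_c.sum()
    t_n = first_t * ref_total / first_t.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.where((c_n > 0) & (t_n > 0), np.log2(t_n / np.maximum(c_n, 1e-300)), np.nan)
        sigma_fc = np.where(
            (c_n > 0) & (t_n > 0),
            np.sqrt(
                total_variance(t_n, sigma_t_) / np.maximum(t_n * LN2, 1e-300) ** 2
                + total_variance(c_n, sigma_c) / np.maximum(c_n * LN2, 1e-300) ** 2
            ),
            np.nan,
        )

    result = pd.DataFrame(
        {
            "gene_id": gene_index,
            "comparison": f"{species_c}_vs_{species_t}",
            "count_control": first_c.astype(int),
            "count_test": first_t.astype(int),
            "log2_fc": log2_fc,
            "fc_ci_low": log2_fc - 2.0 * sigma_fc,
            "fc_ci_high": log2_fc + 2.0 * sigma_fc,
            "chi2": chi2_cols[0],
            "p_rep1": p_cols[0],
            "p_rep2": p_cols[1] if len(p_cols) > 1 else np.nan,
            "p_combined": p_combined,
            "is_de": p_combined < alpha,
            "low_count": low,
        }
    )
    # mean log2 FC across batches drives direction calls downstream
    fc_batches = []
    for pair in pairs:
        c = pair.control.counts.reindex(ids_c).to_numpy(dtype=float)
        t = pair.test.counts.reindex(ids_t).to_numpy(dtype=float)
        ref = common_reference_total(int(c.sum()), int(t.sum()))
        cn, tn = c * ref / c.sum(), t * ref / t.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            fc_batches.append(
                np.where((cn > 0) & (tn > 0), np.log2(tn / np.maximum(cn, 1e-300)), np.nan)
            )
    stacked = np.column_stack(fc_batches)
    n_def = np.isfinite(stacked).sum(axis=1)
    with np.errstate(invalid="ignore"):
        result["log2_fc_mean"] = np.where(
            n_def > 0, np.nansum(np.where(np.isfinite(stacked), stacked, 0.0), axis=1) / np.maximum(n_def, 1), np.nan
        )
    return result


def estimate_fdr(n_tested: int, n_de: int, replicate_de_fraction: float) -> float:
    """Expected replicate false positives over observed DE calls.

    The replicate DE fraction at the same alpha estimates the per-gene false
    call rate under the null; multiplied by the number of genes tested it
    gives the expected false positives among the DE calls.
    """
    if n_de == 0:
        return float("nan")
    if not 0.0 <= replicate_de_fraction <= 1.0:
        raise ValueError("replicate_de_fraction must be in [0, 1]")
    return replicate_de_fraction * n_tested / n_de
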
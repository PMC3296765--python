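"""Between-sample normalization by median-ratio slope and midpoint-projected
distribution means.

The ratio of total library sizes is not a safe scaling factor: a handful of
highly expressed outlier genes can move the total by themselves. The slope m
between a control and a test sample is instead the median of per-gene
test/control count ratios, which a single outlier cannot move.

The per-gene null means (mu_C, mu_T) are found by projecting the observed
count pair (C_g, T_g) onto the line y = m x and taking the midpoint of the
segment bounded by (C_g, C_g m) and (T_g/m, T_g). Both samples get equal
weight regardless of sequencing depth, and the raw counts are never rescaled
(their Poisson variance must stay interpretable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data_io import CountTable


class NormalizationError(ValueError):
    """No usable genes for slope estimation, or an invalid slope."""


@dataclass
class PairNormalization:
    """Scaling slope and per-gene midpoint means for one sample pair."""

    slope_m: float
    gene_means: pd.DataFrame  # columns mu_C, mu_T, indexed by gene_id

    def __post_init__(self) -> None:
        if not self.slope_m > 0:
            raise NormalizationError(f"slope must be positive, got {self.slope_m}")


def median_ratio_slope(
    control: CountTable | pd.Series,
    test: CountTable | pd.Series,
    genes: Iterable[str] | None = None,
    min_count: int = 0,
) -> float:
    """Median of per-gene test/control count ratios.

    Genes with a zero control count (undefined ratio) or absent from either
    sample are excluded. ``min_count`` optionally restricts to genes whose
    control count meets a threshold.
    """
    c = control.counts if isinstance(control, CountTable) else control
    t = test.counts if isinstance(test, CountTable) else test
    if genes is not None:
        idx = pd.Index(genes)
        c, t = c.reindex(idx), t.reindex(idx)
    common = c.index.intersection(t.index)
    c, t = c.loc[common].astype(float), t.loc[common].astype(float)
    keep = (c > 0) & (c >= min_count) & c.notna() & t.notna()
    if not keep.any():
        raise NormalizationError("no genes with a defined test/control ratio")
    m = float(np.median(t[keep] / c[keep]))
    if m <= 0:
        raise NormalizationError(f"degenerate slope m={m}; samples share no expressed genes")
    return m


def distribution_means(c_g: float, t_g: float, m: float) -> tuple[float, float]:
    """Midpoint-projected null means (mu_C, mu_T) with mu_T = m * mu_C."""
    if m <= 0:
        raise ValueError(f"slope must be positive, got {m}")
    mu_c = (c_g + t_g / m) / 2.0
    mu_t = (c_g * m + t_g) / 2.0
    return mu_c, mu_t


def distribution_means_vector(
    c: np.ndarray | pd.Series, t: np.ndarray | pd.Series, m: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`distribution_means` over aligned count arrays."""
    if m <= 0:
        raise ValueError(f"slope must be positive, got {m}")
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    return (c + t / m) / 2.0, (c * m + t) / 2.0


def normalize_pair(
    control: CountTable,
    test: CountTable,
    genes: Iterable[str] | None = None,
) -> PairNormalization:
    """Slope plus midpoint means for every gene shared by the two samples."""
    m = median_ratio_slope(control, test, genes=genes)
    common = control.counts.index.intersection(test.counts.index)
    if genes is not None:
        common = common.intersection(pd.Index(genes))
    c = control.counts.loc[common]
    t = test.counts.loc[common]
    mu_c, mu_t = distribution_means_vector(c, t, m)
    means = pd.DataFrame({"mu_C": mu_c, "mu_T": mu_t}, index=common)
    return PairNormalization(slope_m=m, gene_means=means)


def size_normalized_count(
    count: float, sample_total: int, reference_total: float
) -> float:
    """Rescale a count to a common library size (for fold changes only)."""
    if sample_total <= 0:
        raise ValueError("sample_total must be positive")
    return count * reference_total / sample_total


def common_reference_total(total_a: int, total_b: int) -> float:
    """Geometric mean of two library sizes; fold changes are invariant to the
    choice of common reference, this one keeps both rescalings mild."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    return math.sqrt(float(total_a) * float(total_b))
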
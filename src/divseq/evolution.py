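"""Downstream evolutionary analyses: lineage assignment of expression
changes, the expression-divergence molecular clock, and sample clustering.

Assigning a DE call to a phylogenetic branch requires that the change be
significant with a consistent direction in *every* pairwise comparison the
branch separates — a conservative rule, since genuine lineage-fixed changes
must show up against each species on the other side of the split.

The clock analysis regresses the variance of per-gene log2 fold changes on
the intergenic substitution rate separating the two samples; replicate
self-comparisons enter at rate 0, so the intercept is the replicate
(zero-divergence) variance and the slope is the expression divergence rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
import statsmodels.formula.api as smf

from .de_test import chi2_statistic, p_value
from .normalization import median_ratio_slope

#: Intergenic substitution rates between the four sequenced yeasts
#: (distance of each comparison on the clock's x-axis).
YEAST_SUBSTITUTION_RATES: dict[frozenset[str], float] = {
    frozenset({"cerevisiae", "paradoxus"}): 0.231,
    frozenset({"cerevisiae", "mikatae"}): 0.394,
    frozenset({"cerevisiae", "bayanus"}): 0.556,
    frozenset({"paradoxus", "mikatae"}): 0.359,
    frozenset({"paradoxus", "bayanus"}): 0.521,
    frozenset({"mikatae", "bayanus"}): 0.538,
}


@dataclass(frozen=True)
class Branch:
    """A branch of the species tree, defined by the bipartition it induces."""

    name: str
    side: frozenset[str]  # focal side ("up" means higher expression here)
    other: frozenset[str]

    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a in sorted(self.side) for b in sorted(self.other)]


@dataclass
class Phylogeny:
    """Rooted 4-taxon topology ((cer,par),(mik,bay)) by default."""

    taxa: list[str]
    branches: list[Branch]

    @classmethod
    def yeast(cls) -> "Phylogeny":
        taxa = ["cerevisiae", "paradoxus", "mikatae", "bayanus"]
        branches = [
            Branch(sp, frozenset({sp}), frozenset(t for t in taxa if t != sp)) for sp in taxa
        ]
        branches.append(
            Branch(
                "cerevisiae+paradoxus",
                frozenset({"cerevisiae", "paradoxus"}),
                frozenset({"mikatae", "bayanus"}),
            )
        )
        return cls(taxa=taxa, branches=branches)


def _signed_fc(table: pd.DataFrame, toward: str, pair: tuple[str, str]) -> pd.Series:
    """log2 FC oriented so positive means ``toward`` is the higher species."""
    control, test = pair
    col = "log2_fc_mean" if "log2_fc_mean" in table.columns else "log2_fc"
    fc = table.set_index("gene_id")[col]
    return fc if test == toward else -fc


def assign_lineage(
    de_tables: Mapping[tuple[str, str], pd.DataFrame],
    phylogeny: Phylogeny,
    alpha: float = 0.01,
) -> dict[str, list[tuple[str, str]]]:
    """Assign DE genes to branches of the phylogeny.

    ``de_tables`` maps ordered (control, test) species pairs to result
    tables from :func:`divseq.de_test.call_de` over the core genes. A gene
    lands on a branch iff every pairwise comparison split by that branch is
    significant at ``alpha`` with all fold changes pointing the same way;
    the direction (up/down) refers to the branch's focal side. A gene may be
    assigned to several branches.
    """
    lookup: dict[frozenset[str], tuple[tuple[str, str], pd.DataFrame]] = {
        frozenset(pair): (pair, tbl) for pair, tbl in de_tables.items()
    }
    out: dict[str, list[tuple[str, str]]] = {}
    for branch in phylogeny.branches:
        needed = branch.pairs()
        for a, b in needed:
            if frozenset({a, b}) not in lookup:
                raise ValueError(f"missing DE table for {a} vs {b}")
        sig = None
        fcs = []
        for a, b in needed:
            pair, tbl = lookup[frozenset({a, b})]
            indexed = tbl.set_index("gene_id")
            this_sig = indexed["p_combined"] < alpha
            sig = this_sig if sig is None else (sig & this_sig)
            fcs.append(_signed_fc(tbl, toward=a, pair=pair))
        fc_mat = pd.concat(fcs, axis=1)
        all_up = (fc_mat > 0).all(axis=1)
        all_down = (fc_mat < 0).all(axis=1)
        consistent = sig & (all_up | all_down)
        out[branch.name] = [
            (gene, "up" if all_up.loc[gene] else "down")
            for gene in consistent.index[consistent]
        ]
    return out


def lineage_summary(assignments: Mapping[str, Sequence[tuple[str, str]]]) -> pd.DataFrame:
    rows = [
        {
            "branch": branch,
            "n_genes": len(genes),
            "n_up": sum(1 for _, d in genes if d == "up"),
            "n_down": sum(1 for _, d in genes if d == "down"),
        }
        for branch, genes in assignments.items()
    ]
    return pd.DataFrame(rows)


@dataclass
class DivergenceFit:
    """OLS fit of var(log2 FC) against substitution rate."""

    points: pd.DataFrame  # columns: rate, var_log2fc, n_genes
    slope: float
    intercept: float
    r2: float
    class_label: str = "all"
    stderr: float = float("nan")


def divergence_points(
    fc_vectors: Mapping[object, Sequence[float]],
    rates: Mapping[object, float],
) -> pd.DataFrame:
    """Per-comparison (rate, variance of log2 FC) points for the clock fit.

    Genes with undefined fold change (NaN from zero counts) are excluded
    rather than imputed.
    """
    rows = []
    for key, fcs in fc_vectors.items():
        fcs = np.asarray(fcs, dtype=float)
        fcs = fcs[np.isfinite(fcs)]
        if fcs.size < 2:
            raise ValueError(f"comparison {key!r} has <2 defined fold changes")
        rows.append(
            {"rate": float(rates[key]), "var_log2fc": float(fcs.var(ddof=1)), "n_genes": fcs.size}
        )
    return pd.DataFrame(rows)


def divergence_regression(
    fc_vectors: Mapping[object, Sequence[float]] | None = None,
    rates: Mapping[object, float] | None = None,
    points: pd.DataFrame | None = None,
    class_label: str = "all",
) -> DivergenceFit:
    """Least-squares clock fit; slope = divergence rate, intercept =
    zero-divergence (replicate) variance."""
    if points is None:
        if fc_vectors is None or rates is None:
            raise ValueError("provide either fc_vectors+rates or points")
        points = divergence_points(fc_vectors, rates)
    if len(points) < 3:
        raise ValueError(f"need at least 3 points for the clock fit, got {len(points)}")
    fit = stats.linregress(points["rate"], points["var_log2fc"])
    return DivergenceFit(
        points=points.reset_index(drop=True),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        class_label=class_label,
        stderr=float(fit.stderr),
    )


def compare_class_slopes(fit_a: DivergenceFit, fit_b: DivergenceFit) -> float:
    """Test of slope equality between two gene classes (analysis of
    covariance): p-value of the class-by-rate interaction term."""
    if len(fit_a.points) < 3 or len(fit_b.points) < 3:
        raise ValueError("each class needs at least 3 points")
    df = pd.concat(
        [
            fit_a.points.assign(gene_class=fit_a.class_label or "A"),
            fit_b.points.assign(gene_class=(fit_b.class_label or "B") + "_"),
        ],
        ignore_index=True,
    )
    model = smf.ols("var_log2fc ~ rate * gene_class", data=df).fit()
    interaction = [t for t in model.pvalues.index if ":" in t]
    return float(model.pvalues[interaction[0]])


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray
    distances: pd.DataFrame = field(repr=False, default=None)


def cluster_samples(expression: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Hierarchical clustering of samples on 1 - Spearman correlation.

    ``expression`` has genes as rows and samples as columns. Rank
    correlation makes the distance invariant to monotone transforms, so raw
    or log counts give the same tree.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    constant = expression.nunique(axis=0) <= 1
    if constant.any():
        raise ValueError(
            f"constant expression vector for sample {expression.columns[constant][0]!r}"
        )
    corr = expression.corr(method="spearman")
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    condensed = squareform(dist.values, checks=False)
    return Dendrogram(
        labels=list(expression.columns),
        linkage_matrix=linkage(condensed, method=method),
        distances=dist,
    )


def paralog_expression_contrast(
    candidates: Sequence[tuple[str, tuple[str, str]]],
    reference_counts: pd.Series,
    target_counts: pd.Series,
    diverged_copy: Mapping[str, str],
    sigma_reference: float,
    sigma_target: float,
    one_to_one_genes: Sequence[str] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Classify each paralog copy's expression against the single reference
    ortholog (heir-and-a-spare analysis).

    The scaling slope between the two species comes from their 1:1 genes
    (``one_to_one_genes``; all shared genes when omitted); each copy is then
    tested against the reference gene with the chi-square machinery and
    classified as consistent / significantly_below / significantly_above.
    ``diverged_copy`` names the more sequence-diverged paralog per gene
    (from an upstream phylogenetic analysis); genes without an ordering are
    skipped with a warning.
    """
    m = median_ratio_slope(reference_counts, target_counts, genes=one_to_one_genes)

    def classify(c_ref: float, t_copy: float) -> str:
        x2 = chi2_statistic(c_ref, t_copy, m, sigma_reference, sigma_target)
        if p_value(x2) >= alpha:
            return "consistent"
        return "significantly_below" if t_copy < c_ref * m else "significantly_above"

    rows = []
    for gene, pair in candidates:
        if gene not in diverged_copy:
            warnings.warn(f"no divergence ordering for {gene}; skipped", stacklevel=2)
            continue
        div = diverged_copy[gene]
        if div not in pair:
            raise ValueError(f"{div!r} is not a paralog of {gene!r}")
        cons = pair[0] if pair[1] == div else pair[1]
        c_ref = float(reference_counts.get(gene, np.nan))
        if not np.isfinite(c_ref):
            warnings.warn(f"{gene} missing from reference counts; skipped", stacklevel=2)
            continue
        rows.append(
            {
                "gene_id": gene,
                "diverged_copy": div,
                "conserved_copy": cons,
                "diverged_class": classify(c_ref, float(target_counts.get(div, 0.0))),
                "conserved_class": classify(c_ref, float(target_counts.get(cons, 0.0))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "diverged_copy", "conserved_copy", "diverged_class", "conserved_class",
        ],
    )
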
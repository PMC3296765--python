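import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from divseq.evolution import (
    Phylogeny,
    YEAST_SUBSTITUTION_RATES,
    assign_lineage,
    cluster_samples,
    compare_class_slopes,
    divergence_points,
    divergence_regression,
    lineage_summary,
    paralog_expression_contrast,
)

SPECIES = ["cerevisiae", "paradoxus", "mikatae", "bayanus"]


def make_tables(fc_by_gene, p_by_gene):
    """Build the six pairwise DE tables from per-gene dicts keyed by
    unordered species pair; fc is oriented test-minus-control with the
    pair ordered as in SPECIES."""
    tables = {}
    for i, a in enumerate(SPECIES):
        for b in SPECIES[i + 1:]:
            rows = []
            for gene in fc_by_gene:
                fc = fc_by_gene[gene].get((a, b), 0.0)
                p = p_by_gene[gene].get((a, b), 1.0)
                rows.append({"gene_id": gene, "log2_fc": fc, "p_combined": p})
            tables[(a, b)] = pd.DataFrame(rows)
    return tables


class TestAssignLineage:
    def pairs_with(self, species):
        return [(a, b) for a in SPECIES for b in SPECIES if a < b or True]

    def test_terminal_branch_up(self):
        # gene higher in cerevisiae vs each other species
        fc = {"G1": {}}
        p = {"G1": {}}
        for other in SPECIES[1:]:
            fc["G1"][("cerevisiae", other)] = -2.0  # test (other) lower
            p["G1"][("cerevisiae", other)] = 1e-5
        tables = make_tables(fc, p)
        out = assign_lineage(tables, Phylogeny.yeast(), alpha=0.01)
        assert ("G1", "up") in out["cerevisiae"]
        assert all(("G1", d) not in out[b] for b in ("paradoxus", "mikatae", "bayanus") for d in ("up", "down"))

    def test_missing_one_comparison_unassigned(self):
        # significant vs two species but not the third
        fc = {"G2": {("cerevisiae", "paradoxus"): -1.0, ("cerevisiae", "bayanus"): -1.0,
                     ("cerevisiae", "mikatae"): -1.0}}
        p = {"G2": {("cerevisiae", "paradoxus"): 1e-4, ("cerevisiae", "bayanus"): 1e-4,
                    ("cerevisiae", "mikatae"): 0.2}}
        out = assign_lineage(make_tables(fc, p), Phylogeny.yeast(), alpha=0.01)
        assert all(("G2", d) not in genes for genes in out.values() for d in ("up", "down"))

    def test_inconsistent_direction_unassigned(self):
        fc = {"G3": {("cerevisiae", "paradoxus"): -1.0, ("cerevisiae", "mikatae"): 1.0,
                     ("cerevisiae", "bayanus"): -1.0}}
        p = {"G3": {k: 1e-6 for k in fc["G3"]}}
        out = assign_lineage(make_tables(fc, p), Phylogeny.yeast(), alpha=0.01)
        assert all(("G3", d) not in genes for genes in out.values() for d in ("up", "down"))

    def test_internal_branch_requires_all_cross_pairs(self):
        # {cer,par} both higher than {mik,bay}: 4 cross-split pairs
        fc, p = {"G4": {}}, {"G4": {}}
        for a in ("cerevisiae", "paradoxus"):
            for b in ("mikatae", "bayanus"):
                fc["G4"][(a, b)] = -1.5
                p["G4"][(a, b)] = 1e-6
        out = assign_lineage(make_tables(fc, p), Phylogeny.yeast(), alpha=0.01)
        assert ("G4", "up") in out["cerevisiae+paradoxus"]

    def test_down_direction_and_multi_branch(self):
        # lower in bayanus vs all (bayanus terminal, down) — and since the
        # change is seen from every other species it is exactly one branch
        fc, p = {"G5": {}}, {"G5": {}}
        for a in ("cerevisiae", "paradoxus", "mikatae"):
            fc["G5"][(a, "bayanus")] = -2.0  # bayanus (test) lower
            p["G5"][(a, "bayanus")] = 1e-8
        out = assign_lineage(make_tables(fc, p), Phylogeny.yeast(), alpha=0.01)
        assert ("G5", "down") in out["bayanus"]

    def test_assignments_recheck_against_tables(self):
        rng = np.random.default_rng(3)
        fc, p = {}, {}
        for i in range(50):
            g = f"r{i}"
            fc[g], p[g] = {}, {}
            for a_i, a in enumerate(SPECIES):
                for b in SPECIES[a_i + 1:]:
                    fc[g][(a, b)] = float(rng.normal(0, 1.5))
                    p[g][(a, b)] = float(rng.uniform(0, 0.05))
        tables = make_tables(fc, p)
        out = assign_lineage(tables, Phylogeny.yeast(), alpha=0.01)
        for branch in Phylogeny.yeast().branches:
            for gene, direction in out[branch.name]:
                for a, b in branch.pairs():
                    key = (a, b) if (a, b) in tables else (b, a)
                    row = tables[key].set_index("gene_id").loc[gene]
                    assert row["p_combined"] < 0.01
                    oriented = row["log2_fc"] if key[1] == a else -row["log2_fc"]
                    assert (oriented > 0) == (direction == "up")

    def test_missing_table_is_error(self):
        fc = {"G": {}}
        p = {"G": {}}
        tables = make_tables(fc, p)
        del tables[("cerevisiae", "paradoxus")]
        with pytest.raises(ValueError, match="missing DE table"):
            assign_lineage(tables, Phylogeny.yeast())

    def test_summary_counts(self):
        out = {"cerevisiae": [("a", "up"), ("b", "down")], "bayanus": []}
        summary = lineage_summary(out).set_index("branch")
        assert summary.loc["cerevisiae", "n_genes"] == 2
        assert summary.loc["cerevisiae", "n_up"] == 1
        assert summary.loc["bayanus", "n_genes"] == 0


class TestDivergenceRegression:
    def test_exact_linear_points(self):
        rates = dict(enumerate([0.0, 0.0, 0.231, 0.394, 0.556]))
        rng = np.random.default_rng(0)
        fcs = {
            k: rng.normal(0, np.sqrt(0.5 + 2.0 * r), size=200_000) for k, r in rates.items()
        }
        fit = divergence_regression(fcs, rates)
        assert fit.slope == pytest.approx(2.0, rel=0.05)
        assert fit.intercept == pytest.approx(0.5, rel=0.05)
        assert fit.r2 > 0.95

    def test_constant_variance_zero_slope(self):
        points = pd.DataFrame(
            {"rate": [0.0, 0.2, 0.4, 0.6], "var_log2fc": [1.0, 1.0, 1.0, 1.0], "n_genes": [10] * 4}
        )
        fit = divergence_regression(points=points)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_canonical_rates_fixture(self):
        assert len(YEAST_SUBSTITUTION_RATES) == 6
        assert YEAST_SUBSTITUTION_RATES[frozenset({"cerevisiae", "bayanus"})] == 0.556

    def test_nan_fold_changes_excluded(self):
        fcs = {0: [0.1, -0.1, np.nan, 0.2], 1: [1.0, -1.0, 0.5], 2: [2.0, -2.0, 0.1]}
        rates = {0: 0.0, 1: 0.3, 2: 0.6}
        pts = divergence_points(fcs, rates)
        assert pts.loc[0, "n_genes"] == 3

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            divergence_regression(points=pd.DataFrame({"rate": [0, 1], "var_log2fc": [0, 1]}))


class TestCompareClassSlopes:
    def make_fit(self, slope, noise_sd, seed, label):
        rng = np.random.default_rng(seed)
        rates = np.array([0.0, 0.0, 0.231, 0.359, 0.394, 0.521, 0.538, 0.556])
        var = 0.5 + slope * rates + rng.normal(0, noise_sd, size=rates.size)
        points = pd.DataFrame({"rate": rates, "var_log2fc": var, "n_genes": 1000})
        return divergence_regression(points=points, class_label=label)

    def test_identical_classes_no_interaction(self):
        a = self.make_fit(2.0, 0.01, 1, "A")
        b = self.make_fit(2.0, 0.01, 2, "B")
        assert compare_class_slopes(a, b) > 0.1

    def test_doubled_slope_detected(self):
        a = self.make_fit(2.0, 0.01, 3, "A")
        b = self.make_fit(4.0, 0.01, 4, "B")
        assert compare_class_slopes(a, b) < 0.01

    def test_single_point_class_is_error(self):
        a = self.make_fit(2.0, 0.01, 5, "A")
        b = pd.DataFrame({"rate": [0.1], "var_log2fcx": [1.0]})
        from divseq.evolution import DivergenceFit

        bad = DivergenceFit(points=pd.DataFrame({"rate": [0.1], "var_log2fc": [1.0], "n_genes": [5]}),
                            slope=0, intercept=0, r2=0, class_label="B")
        with pytest.raises(ValueError):
            compare_class_slopes(a, bad)


class TestClusterSamples:
    def test_duplicate_samples_merge_first(self):
        rng = np.random.default_rng(7)
        base = rng.lognormal(3, 1, 100)
        expr = pd.DataFrame(
            {
                "a1": base,
                "a2": base,  # identical ranks -> distance 0
                "b": rng.lognormal(3, 1, 100),
                "c": rng.lognormal(3, 1, 100),
            }
        )
        tree = cluster_samples(expr)
        first = tree.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        x = np.arange(50, dtype=float)
        expr = pd.DataFrame({"up": x, "down": -x, "noise": np.sin(x) * 10 + x * 0.01})
        tree = cluster_samples(expr)
        assert tree.distances.loc["up", "down"] == pytest.approx(2.0)

    def test_clock_topology_recovered(self):
        rng = np.random.default_rng(11)
        n = 2000
        root = rng.normal(0, 1, n)

        def evolve(parent, dist):
            return parent + rng.normal(0, np.sqrt(dist), n)

        anc_cp = evolve(root, 0.1)
        expr = pd.DataFrame(
            {
                "cer": evolve(anc_cp, 0.1),
                "par": evolve(anc_cp, 0.1),
                "mik": evolve(root, 0.25),
                "bay": evolve(root, 0.3),
            }
        )
        tree = cluster_samples(expr)
        clusters = fcluster(tree.linkage_matrix, t=2, criterion="maxclust")
        by_label = dict(zip(tree.labels, clusters))
        assert by_label["cer"] == by_label["par"] != by_label["bay"]

    def test_constant_vector_rejected(self):
        expr = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3], "c": [3, 1, 2]})
        with pytest.raises(ValueError, match="constant"):
            cluster_samples(expr)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestParalogContrast:
    def setup_counts(self, rng, n_background=201):
        genes = [f"g{i}" for i in range(n_background)]
        ref = pd.Series(rng.poisson(500, n_background), index=genes, dtype=float)
        target = pd.Series(rng.poisson(500, n_background), index=genes, dtype=float)
        return ref, target

    def test_planted_heir_and_spare_pattern(self):
        rng = np.random.default_rng(23)
        ref, target = self.setup_counts(rng)
        candidates, diverged = [], {}
        for i in range(14):
            gene = f"dup{i}"
            ref[gene] = 1000.0
            heir, spare = f"heir{i}", f"spare{i}"
            target[heir] = 1000.0
            # 10 of 14 diverged copies drop to 10% of the reference level
            target[spare] = 100.0 if i < 10 else 1000.0
            candidates.append((gene, (heir, spare)))
            diverged[gene] = spare
        out = paralog_expression_contrast(
            candidates, ref, target, diverged, 0.16, 0.16,
            one_to_one_genes=[g for g in ref.index if g.startswith("g")],
        )
        assert (out["diverged_class"] == "significantly_below").sum() == 10
        assert (out["conserved_class"] == "consistent").all()

    def test_both_copies_at_reference_level(self):
        rng = np.random.default_rng(5)
        ref, target = self.setup_counts(rng)
        ref["dup"] = 800.0
        target["c1"] = 800.0
        target["c2"] = 800.0
        out = paralog_expression_contrast(
            [("dup", ("c1", "c2"))], ref, target, {"dup": "c2"}, 0.16, 0.16
        )
        assert out.iloc[0]["diverged_class"] == "consistent"
        assert out.iloc[0]["conserved_class"] == "consistent"

    def test_missing_ordering_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        ref, target = self.setup_counts(rng)
        with pytest.warns(UserWarning, match="no divergence ordering"):
            out = paralog_expression_contrast(
                [("g0", ("x", "y"))], ref, target, {}, 0.16, 0.16
            )
        assert out.empty
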
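import pandas as pd
import pytest

from divseq.data_io import CountTable, GeneAnnotation, OrthologSet, Sample
from divseq.simulator import SimulationSpec, simulate_dataset


def make_table(counts: dict, sample_id="s1", species="cerevisiae", rep=1, batch="day1",
               kind="biological") -> CountTable:
    return CountTable(
        Sample(sample_id, species, rep, batch, kind),
        pd.Series(counts, dtype="int64"),
    )


@pytest.fixture(scope="session")
def yeast_species():
    return ["cerevisiae", "paradoxus", "mikatae", "bayanus"]


@pytest.fixture
def ortholog_fixture(yeast_species):
    """Ten reference genes with hand-chosen annotation defects.

    Genes g0-g6 pass every inclusion criterion in all four species; g7 is
    1:2 in bayanus, g8 has a too-short mikatae ortholog (length ratio 0.85),
    g9 has unique_fraction 0.80 in paradoxus.
    """
    ref = "cerevisiae"
    others = [s for s in yeast_species if s != ref]
    entries = {}
    annotations = {sp: {} for sp in yeast_species}
    for i in range(10):
        gene = f"y{i}"
        entries[gene] = {sp: [f"{sp[:3]}_{i}"] for sp in others}
        annotations[ref][gene] = GeneAnnotation(gene, ref, 1000, True, 0.95)
        for sp in others:
            length, uf = 1000, 0.95
            if gene == "y8" and sp == "mikatae":
                length = 850
            if gene == "y9" and sp == "paradoxus":
                uf = 0.80
            annotations[sp][f"{sp[:3]}_{i}"] = GeneAnnotation(f"{sp[:3]}_{i}", sp, length, True, uf)
    entries["y7"]["bayanus"] = ["bay_7", "bay_7b"]
    annotations["bayanus"]["bay_7b"] = GeneAnnotation("bay_7b", "bayanus", 1000, True, 0.95)
    return OrthologSet(reference_species=ref, entries=entries), annotations


@pytest.fixture(scope="session")
def null_pair_dataset():
    """Two species, two batches each, no true DE, uniform over-dispersion."""
    spec = SimulationSpec(n_genes=4000, overdispersion_u=0.16, de_fraction=0.0, seed=42)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def de_dataset():
    """Two species with 10% of genes shifted by 2 log2 units."""
    spec = SimulationSpec(
        n_genes=4000, overdispersion_u=0.16, de_fraction=0.1,
        effect_model="fixed", effect_size=2.0, seed=43,
    )
    return simulate_dataset(spec)


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
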
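"""Inclusion criteria for measurable 1:1 orthologs, core genes, and
stringent duplication candidates.

A gene is a *measurable* 1:1 ortholog in a species when its annotation is
trustworthy enough that a raw unique-read count means the same thing there as
it does in the reference species: exactly one ortholog, a complete ORF, an
annotated length within 90-110% of the reference length, at least 90% of its
aligned reads aligning uniquely, and a coding biotype (non-coding RNAs
reproduce too poorly across replicates to test). *Core* genes pass in every
species and are the common currency of all cross-species comparisons.
"""

from __future__ import annotations

from typing import Callable, Mapping

from .data_io import DataError, GeneAnnotation, OrthologSet

LENGTH_RATIO_LOW = 0.90
LENGTH_RATIO_HIGH = 1.10
MIN_UNIQUE_FRACTION = 0.90
MIN_DUPLICATION_COVERAGE = 0.60

AnnotationMap = Mapping[str, Mapping[str, GeneAnnotation]]  # species -> gene_id -> record


def measurable_ortholog(
    gene: str,
    species: str,
    orthologs: OrthologSet,
    annotations: AnnotationMap,
) -> bool:
    """Whether ``gene`` (a reference-species ID) is measurable in ``species``."""
    ref_species = orthologs.reference_species
    ref_ann = annotations.get(ref_species, {}).get(gene)
    if ref_ann is None:
        return False
    if species == ref_species:
        ann = ref_ann
    else:
        if not orthologs.is_one_to_one(gene, species):
            return False
        ortho_id = orthologs.ortholog(gene, species)
        ann = annotations.get(species, {}).get(ortho_id)
        if ann is None:
            raise DataError(f"ortholog {ortho_id!r} of {gene!r} has no annotation in {species}")
    ratio = ann.annotated_length / ref_ann.annotated_length
    return (
        ann.complete_orf
        and LENGTH_RATIO_LOW <= ratio <= LENGTH_RATIO_HIGH
        and ann.unique_fraction >= MIN_UNIQUE_FRACTION
        and ref_ann.biotype == "coding"
        and ann.biotype == "coding"
    )


def measurable_genes(
    orthologs: OrthologSet,
    annotations: AnnotationMap,
    species: str,
) -> set[str]:
    """All reference genes measurable in ``species``."""
    return {
        g for g in orthologs.entries if measurable_ortholog(g, species, orthologs, annotations)
    }


def comparison_genes(
    orthologs: OrthologSet,
    annotations: AnnotationMap,
    species_a: str,
    species_b: str,
) -> set[str]:
    """Genes measurable in both species of a pairwise comparison."""
    return measurable_genes(orthologs, annotations, species_a) & measurable_genes(
        orthologs, annotations, species_b
    )


def core_gene_set(
    orthologs: OrthologSet,
    annotations: AnnotationMap,
    species_list: list[str],
) -> set[str]:
    """Genes measurable in *every* listed species; sets ``core_flags``."""
    if len(species_list) < 2:
        raise ValueError("core gene set needs at least 2 species")
    core = set(orthologs.entries)
    for sp in species_list:
        core &= measurable_genes(orthologs, annotations, sp)
    orthologs.core_flags = {g: (g in core) for g in orthologs.entries}
    return core


def duplication_candidates(
    orthologs: OrthologSet,
    coverage: Mapping[tuple[str, str], float],
    species: str,
    extra_filter: Callable[[str, tuple[str, str]], bool] | None = None,
) -> list[tuple[str, tuple[str, str]]]:
    """Reference genes with exactly two orthologs in ``species`` where both
    copies cover > 60% of the reference gene.

    ``coverage`` maps (reference_gene, paralog_id) to the fraction of the
    reference gene covered; it is an input because alignment is upstream of
    this package. ``extra_filter`` hooks in any additional screening.
    """
    out: list[tuple[str, tuple[str, str]]] = []
    for gene, mapping in orthologs.entries.items():
        paralogs = mapping.get(species, [])
        if len(paralogs) != 2:
            continue
        pair = (paralogs[0], paralogs[1])
        covs = [coverage.get((gene, p), 0.0) for p in pair]
        if not all(c > MIN_DUPLICATION_COVERAGE for c in covs):
            continue
        if extra_filter is not None and not extra_filter(gene, pair):
            continue
        out.append((gene, pair))
    return out
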
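"""Shared data model and TSV/JSON input-output.

Count tables are raw unique-read integers per gene — never length-normalized
(RPKM discards the Poisson information the test statistic needs). All
cross-species structures are keyed by reference-species gene IDs; ortholog IDs
in other species are carried as attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

NA = "NA"

#: Column order of a differential-expression result table.
RESULT_COLUMNS = [
    "gene_id",
    "comparison",
    "count_control",
    "count_test",
    "log2_fc",
    "fc_ci_low",
    "fc_ci_high",
    "chi2",
    "p_rep1",
    "p_rep2",
    "p_combined",
    "is_de",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class Sample:
    """One sequenced RNA sample.

    ``batch`` is the growth-day label: tests are only run between samples of
    the same batch, because day effects masquerade as expression changes.
    """

    sample_id: str
    species: str
    replicate_index: int
    batch: str
    kind: str = "biological"

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise DataError(f"replicate_index must be >= 1, got {self.replicate_index}")
        if not self.batch:
            raise DataError(f"sample {self.sample_id!r}: batch label must be non-empty")
        if self.kind not in ("technical", "biological"):
            raise DataError(f"sample {self.sample_id!r}: unknown kind {self.kind!r}")


@dataclass
class CountTable:
    """Per-sample gene -> unique-read-count mapping."""

    sample: Sample
    counts: pd.Series  # int64, indexed by gene_id

    def __post_init__(self) -> None:
        counts = pd.Series(self.counts, dtype="int64")
        if (counts < 0).any():
            bad = counts.index[counts < 0][0]
            raise DataError(f"negative count for gene {bad!r}")
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise DataError(f"duplicate gene_id {dup!r}")
        self.counts = counts

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)

    def restrict(self, genes: Iterable[str]) -> "CountTable":
        """Subset to ``genes`` (missing genes are dropped, not zero-filled)."""
        idx = self.counts.index.intersection(pd.Index(genes))
        return CountTable(self.sample, self.counts.loc[idx])


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    species: str
    annotated_length: int
    complete_orf: bool
    unique_fraction: float
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.annotated_length <= 0:
            raise DataError(f"{self.gene_id}: annotated_length must be positive")
        if not 0.0 <= self.unique_fraction <= 1.0:
            raise DataError(f"{self.gene_id}: unique_fraction must be in [0, 1]")


@dataclass
class OrthologSet:
    """Cross-species gene correspondences anchored to a reference species.

    ``entries[ref_gene][species]`` is the (possibly empty) list of ortholog
    IDs; a gene is 1:1 in a species iff that list has exactly one element.
    ``core_flags`` is filled in by the inclusion-criteria filter.
    """

    reference_species: str
    entries: dict[str, dict[str, list[str]]]
    core_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for mapping in self.entries.values():
            for sp in mapping:
                seen.setdefault(sp, None)
        return list(seen)

    def is_one_to_one(self, gene: str, species: str) -> bool:
        if species == self.reference_species:
            return gene in self.entries
        return len(self.entries.get(gene, {}).get(species, [])) == 1

    def ortholog(self, gene: str, species: str) -> str:
        """The single ortholog ID of ``gene`` in ``species`` (must be 1:1)."""
        if species == self.reference_species:
            return gene
        hits = self.entries[gene][species]
        if len(hits) != 1:
            raise DataError(f"{gene} is not 1:1 in {species} ({len(hits)} orthologs)")
        return hits[0]

    def core_genes(self) -> set[str]:
        return {g for g, flag in self.core_flags.items() if flag}


def read_count_table(path: str | Path, sample: Sample) -> CountTable:
    """Read a 2-column TSV (gene_id, count) into a :class:`CountTable`."""
    path = Path(path)
    genes: list[str] = []
    values: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene, raw = parts
            try:
                count = int(raw)
            except ValueError:
                raise DataError(f"{path}:{lineno}: count {raw!r} is not an integer") from None
            if count < 0:
                raise DataError(f"{path}:{lineno}: negative count for {gene!r}")
            genes.append(gene)
            values.append(count)
    series = pd.Series(values, index=pd.Index(genes, name="gene_id"), dtype="int64")
    if series.index.has_duplicates:
        dup = series.index[series.index.duplicated()][0]
        raise DataError(f"{path}: duplicate gene_id {dup!r}")
    return CountTable(sample, series)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", header=False)


def read_ortholog_map(path: str | Path, reference_species: str) -> OrthologSet:
    """Read an ortholog map TSV.

    Header: ``gene_id`` followed by one column per non-reference species;
    cells are comma-separated ortholog IDs, empty meaning absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "gene_id":
        raise DataError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if reference_species in df.columns[1:]:
        raise DataError(f"{path}: reference species {reference_species!r} must not be a column")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate reference gene id {dup!r}")
    entries: dict[str, dict[str, list[str]]] = {}
    for row in df.itertuples(index=False):
        gene = row.gene_id
        entries[gene] = {
            sp: [g for g in getattr(row, sp).split(",") if g] for sp in df.columns[1:]
        }
    return OrthologSet(reference_species=reference_species, entries=entries)


def write_ortholog_map(orthologs: OrthologSet, path: str | Path) -> None:
    species = orthologs.species
    with Path(path).open("w") as fh:
        fh.write("\t".join(["gene_id", *species]) + "\n")
        for gene, mapping in orthologs.entries.items():
            cells = [",".join(mapping.get(sp, [])) for sp in species]
            fh.write("\t".join([gene, *cells]) + "\n")


def read_annotations(path: str | Path) -> dict[str, dict[str, GeneAnnotation]]:
    """Read per-gene annotations, returned as species -> gene_id -> record."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "species", "annotated_length", "complete_orf", "unique_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing annotation columns {sorted(missing)}")
    out: dict[str, dict[str, GeneAnnotation]] = {}
    for row in df.itertuples(index=False):
        ann = GeneAnnotation(
            gene_id=row.gene_id,
            species=row.species,
            annotated_length=int(row.annotated_length),
            complete_orf=row.complete_orf.lower() in ("1", "true", "yes"),
            unique_fraction=float(row.unique_fraction),
            biotype=getattr(row, "biotype", "coding") or "coding",
        )
        out.setdefault(ann.species, {})[ann.gene_id] = ann
    return out


def write_annotations(annotations: Mapping[str, Mapping[str, GeneAnnotation]], path: str | Path) -> None:
    rows = []
    for per_gene in annotations.values():
        for ann in per_gene.values():
            rows.append(
                {
                    "gene_id": ann.gene_id,
                    "species": ann.species,
                    "annotated_length": ann.annotated_length,
                    "complete_orf": str(ann.complete_orf).lower(),
                    "unique_fraction": ann.unique_fraction,
                    "biotype": ann.biotype,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a DE result table as TSV; NaN fields (undefined CIs) become "NA"."""
    if results.empty:
        raise DataError("refusing to write an empty result table")
    out = results.reindex(columns=[c for c in RESULT_COLUMNS if c in results.columns])
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if "is_de" in df.columns:
        df["is_de"] = df["is_de"].astype(bool)
    return df


def read_manifest(path: str | Path) -> list[tuple[Sample, Path]]:
    """Read a dataset manifest (JSON or YAML).

    Schema::

        samples:
          - sample_id: cer_r1
            species: cerevisiae
            replicate_index: 1
            batch: day1
            kind: biological        # optional
            counts: counts/cer_r1.tsv

    Count paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out: list[tuple[Sample, Path]] = []
    seen: set[str] = set()
    for entry in data["samples"]:
        sample = Sample(
            sample_id=entry["sample_id"],
            species=entry["species"],
            replicate_index=int(entry["replicate_index"]),
            batch=str(entry["batch"]),
            kind=entry.get("kind", "biological"),
        )
        if sample.sample_id in seen:
            raise DataError(f"{path}: duplicate sample_id {sample.sample_id!r}")
        seen.add(sample.sample_id)
        out.append((sample, path.parent / entry["counts"]))
    return out


def load_dataset(manifest_path: str | Path) -> dict[str, CountTable]:
    """Read every count table named in a manifest, keyed by sample_id."""
    return {
        sample.sample_id: read_count_table(counts_path, sample)
        for sample, counts_path in read_manifest(manifest_path)
    }
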
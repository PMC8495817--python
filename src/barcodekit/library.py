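"""Reference barcode library: domain types and FASTA/TSV readers and writers.

A reference library joins specimen-level marker sequences (one FASTA file per
marker, record ids = specimen ids) to a ranked taxonomy table (TSV with columns
specimen_id, species, genus, family, order). Species names are opaque keys:
no parsing of authorities or infraspecific ranks is attempted.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (uppercase); gaps are not part of a
#: library sequence -- aligned matrices are a separate artefact.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

TAXONOMY_COLUMNS = ("specimen_id", "species", "genus", "family", "order")


class LibraryError(ValueError):
    """Invalid library input (unknown specimen, rank conflict, bad sequence)."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One marker sequence of one specimen, with its ranked taxonomy."""

    specimen_id: str
    marker_id: str
    sequence: str
    species: str
    genus: str
    family: str
    order: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise LibraryError(
                f"empty sequence for ({self.specimen_id}, {self.marker_id})"
            )
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise LibraryError(
                f"non-IUPAC symbols {sorted(bad)} in sequence of "
                f"({self.specimen_id}, {self.marker_id})"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class ReferenceLibrary:
    """A collection of barcode records over an ordered set of markers.

    Invariants checked on construction: (specimen, marker) pairs are unique,
    every record's marker is declared, and the taxonomy is a proper hierarchy
    (each species under one genus, genus under one family, family under one
    order).
    """

    records: list[BarcodeRecord]
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.specimen_id, rec.marker_id)
            if key in seen:
                raise LibraryError(f"duplicate record for {key}")
            seen.add(key)
            if rec.marker_id not in self.markers:
                raise LibraryError(
                    f"record {key} uses undeclared marker {rec.marker_id!r}"
                )
        _check_hierarchy(self.records)

    # -- convenience views -------------------------------------------------

    def records_for_marker(self, marker_id: str) -> list[BarcodeRecord]:
        if marker_id not in self.markers:
            raise LibraryError(f"unknown marker {marker_id!r}")
        return [r for r in self.records if r.marker_id == marker_id]

    def species_of(self) -> dict[str, str]:
        """Map specimen_id -> species over all records."""
        return {r.specimen_id: r.species for r in self.records}

    @property
    def species(self) -> set[str]:
        return {r.species for r in self.records}

    @property
    def specimens(self) -> set[str]:
        return {r.specimen_id for r in self.records}

    def sequence(self, specimen_id: str, marker_id: str) -> str | None:
        for r in self.records:
            if r.specimen_id == specimen_id and r.marker_id == marker_id:
                return r.sequence
        return None


@dataclass(frozen=True)
class LibraryCounts:
    """Whole-library tallies: specimens, taxa, barcodes, per-marker breakdown."""

    n_specimens: int
    n_species: int
    n_genera: int
    n_families: int
    n_barcodes: int
    per_marker: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    n_species_all_markers: int = 0


def _check_hierarchy(records: Iterable[BarcodeRecord]) -> None:
    for child, parent in (("species", "genus"), ("genus", "family"),
                          ("family", "order")):
        mapping: dict[str, str] = {}
        for rec in records:
            c, p = getattr(rec, child), getattr(rec, parent)
            if mapping.setdefault(c, p) != p:
                raise LibraryError(
                    f"taxonomy conflict: {child} {c!r} appears under "
                    f"{parent}s {mapping[c]!r} and {p!r}"
                )


def read_taxonomy(taxonomy_file: str | Path) -> pd.DataFrame:
    """Read the five-column taxonomy TSV (header required, UTF-8)."""
    tax = pd.read_csv(taxonomy_file, sep="\t", dtype=str)
    missing = set(TAXONOMY_COLUMNS) - set(tax.columns)
    if missing:
        raise LibraryError(
            f"taxonomy table {taxonomy_file} lacks columns {sorted(missing)}"
        )
    if tax["specimen_id"].duplicated().any():
        dups = tax.loc[tax["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise LibraryError(f"duplicate specimen ids in taxonomy: {dups}")
    return tax[list(TAXONOMY_COLUMNS)]


def read_library(
    sequence_files: Mapping[str, str | Path],
    taxonomy_file: str | Path,
) -> ReferenceLibrary:
    """Build a ReferenceLibrary from per-marker FASTA files and a taxonomy TSV.

    FASTA record ids must be specimen ids present in the taxonomy table;
    line-wrapping is ignored and sequences are uppercased. Unknown specimens,
    duplicate (specimen, marker) pairs and rank conflicts are fatal.
    """
    tax = read_taxonomy(taxonomy_file)
    by_specimen = {row.specimen_id: row for row in tax.itertuples(index=False)}
    records: list[BarcodeRecord] = []
    for marker_id, path in sequence_files.items():
        for seqrec in SeqIO.parse(str(path), "fasta"):
            row = by_specimen.get(seqrec.id)
            if row is None:
                raise LibraryError(
                    f"FASTA record {seqrec.id!r} in {path} is absent from the "
                    f"taxonomy table"
                )
            records.append(
                BarcodeRecord(
                    specimen_id=seqrec.id,
                    marker_id=marker_id,
                    sequence=str(seqrec.seq),
                    species=row.species,
                    genus=row.genus,
                    family=row.family,
                    order=row.order,
                )
            )
    return ReferenceLibrary(records=records, markers=tuple(sequence_files))


def write_library(
    lib: ReferenceLibrary, out_dir: str | Path, prefix: str = "library"
) -> dict[str, Path]:
    """Write per-marker FASTA files plus the taxonomy TSV.

    Record order is deterministic (sorted by specimen_id then marker_id) so
    outputs are byte-identical across runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    ordered = sorted(lib.records, key=lambda r: (r.specimen_id, r.marker_id))
    for marker in lib.markers:
        path = out_dir / f"{prefix}_{marker}.fasta"
        seqs = [
            SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
            for r in ordered
            if r.marker_id == marker
        ]
        SeqIO.write(seqs, str(path), "fasta")
        written[marker] = path

    tax_rows = sorted(
        {
            (r.specimen_id, r.species, r.genus, r.family, r.order)
            for r in lib.records
        }
    )
    tax_path = out_dir / f"{prefix}_taxonomy.tsv"
    pd.DataFrame(tax_rows, columns=list(TAXONOMY_COLUMNS)).to_csv(
        tax_path, sep="\t", index=False
    )
    written["taxonomy"] = tax_path
    return written


def library_counts(lib: ReferenceLibrary) -> LibraryCounts:
    """Tally specimens, taxa and barcodes; empty libraries give all zeros."""
    per_marker: dict[str, tuple[int, int]] = {}
    species_by_marker: dict[str, set[str]] = defaultdict(set)
    for rec in lib.records:
        species_by_marker[rec.marker_id].add(rec.species)
    for marker in lib.markers:
        n_rec = sum(1 for r in lib.records if r.marker_id == marker)
        per_marker[marker] = (n_rec, len(species_by_marker[marker]))
    if lib.markers:
        all_markers = set.intersection(
            *(species_by_marker[m] for m in lib.markers)
        ) if all(m in species_by_marker for m in lib.markers) else set()
    else:
        all_markers = set()
    return LibraryCounts(
        n_specimens=len(lib.specimens),
        n_species=len(lib.species),
        n_genera=len({r.genus for r in lib.records}),
        n_families=len({r.family for r in lib.records}),
        n_barcodes=len(lib.records),
        per_marker=per_marker,
        n_species_all_markers=len(all_markers),
    )


def reduced_library(
    lib: ReferenceLibrary, required_markers: set[str] | frozenset[str]
) -> ReferenceLibrary:
    """Restrict to species having at least one sequence of every required marker.

    With an empty requirement the library is returned unchanged (a copy); the
    operation is idempotent.
    """
    unknown = set(required_markers) - set(lib.markers)
    if unknown:
        raise LibraryError(f"unknown markers in requirement: {sorted(unknown)}")
    species_by_marker: dict[str, set[str]] = defaultdict(set)
    for rec in lib.records:
        species_by_marker[rec.marker_id].add(rec.species)
    keep = lib.species
    for marker in required_markers:
        keep = keep & species_by_marker[marker]
    return ReferenceLibrary(
        records=[r for r in lib.records if r.species in keep],
        markers=lib.markers,
    )
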
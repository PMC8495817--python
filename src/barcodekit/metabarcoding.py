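"""Bulk-sample metabarcoding: ASV assignment, co-occurrence curation, reports.

The unit of analysis is the ASV (amplicon sequence variant): an exact denoised
amplicon sequence with a count per bulk sample. ASVs are assigned to species
by best semi-global identity against the reference library under minimum
identity/coverage thresholds (defaults 95 and 70), and erroneous ASVs are
collapsed into their more abundant parents by a co-occurrence curation pass
(defaults: minimum relative co-occurrence 0.95, minimum similarity 84,
minimum abundance ratio 1), in the style of post-clustering amplicon curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import ReferenceLibrary
from .pairwise import (
    AlignScoring,
    DEFAULT_SCORING,
    MIN_HIT_COLUMNS,
    pair_stats,
)

logger = logging.getLogger(__name__)


@dataclass
class ASVTable:
    """ASV sequences plus an ASV x sample integer count matrix."""

    sequences: dict[str, str]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.index) - set(self.sequences)
        if missing:
            raise ValueError(f"count rows without a sequence: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("ASV counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class AssignmentConfig:
    """Thresholds for species assignment of ASVs (percent scales)."""

    marker: str
    min_identity: float = 95.0
    min_coverage: float = 70.0

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not 0 <= v <= 100:
                raise ValueError("thresholds must lie in [0, 100]")


@dataclass(frozen=True)
class CurationConfig:
    """Gates of the co-occurrence curation pass."""

    min_cooccurrence: float = 0.95
    min_similarity: float = 84.0
    min_ratio: float = 1.0
    ratio_type: str = "min"  # or "avg"

    def __post_init__(self) -> None:
        if not 0 < self.min_cooccurrence <= 1:
            raise ValueError("min_cooccurrence must lie in (0, 1]")
        if self.ratio_type not in ("min", "avg"):
            raise ValueError("ratio_type must be 'min' or 'avg'")
        if self.min_ratio <= 0:
            raise ValueError("min_ratio must be positive")


@dataclass(frozen=True)
class Assignment:
    """Assignment state of one ASV against the reference library."""

    asv_id: str
    status: str  # assigned | below_threshold | ambiguous
    species: str | None
    best_identity: float
    best_coverage: float


def assign_asvs(
    table: ASVTable,
    lib: ReferenceLibrary,
    cfg: AssignmentConfig,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[Assignment]:
    """Assign each ASV to the species of its best reference hit.

    Best hit = maximum identity, ties broken by higher coverage (both compared
    as exact rationals, ASV as query). If the equally best hits span more than
    one species the ASV is ambiguous; if the best hit fails the identity or
    coverage threshold the ASV is below_threshold.
    """
    refs = sorted(lib.records_for_marker(cfg.marker),
                  key=lambda r: r.specimen_id)
    if not refs:
        raise ValueError(f"library has no records of marker {cfg.marker!r}")
    out: list[Assignment] = []
    for asv_id in table.asv_ids:
        seq = table.sequences[asv_id]
        best_key: tuple[Fraction, Fraction] | None = None
        best_species: set[str] = set()
        best_ident = best_cov = 0.0
        for rec in refs:
            st = pair_stats(seq, rec.sequence, scoring)
            if st.denominator < MIN_HIT_COLUMNS:
                continue  # unalignable reference: no hit
            ident = Fraction(st.identical, st.denominator)
            cov = Fraction(st.a_region_residues, len(seq))
            key = (ident, cov)
            if best_key is None or key > best_key:
                best_key = key
                best_species = {rec.species}
                best_ident = 100.0 * float(ident)
                best_cov = 100.0 * float(cov)
            elif key == best_key:
                best_species.add(rec.species)
        if best_key is None:
            out.append(Assignment(asv_id, "below_threshold", None, 0.0, 0.0))
            continue
        ident_frac, cov_frac = best_key
        meets = (ident_frac * 100 >= Fraction(cfg.min_identity).limit_denominator(10**6)
                 and cov_frac * 100 >= Fraction(cfg.min_coverage).limit_denominator(10**6))
        if not meets:
            out.append(Assignment(asv_id, "below_threshold", None,
                                  best_ident, best_cov))
        elif len(best_species) > 1:
            out.append(Assignment(asv_id, "ambiguous", None,
                                  best_ident, best_cov))
        else:
            out.append(Assignment(asv_id, "assigned", next(iter(best_species)),
                                  best_ident, best_cov))
    return out


def curate(
    table: ASVTable,
    cfg: CurationConfig = CurationConfig(),
    scoring: AlignScoring = DEFAULT_SCORING,
) -> tuple[ASVTable, dict[str, str]]:
    """Collapse putative erroneous ASVs into more abundant parents.

    ASVs are processed in increasing total-count order (ties by asv_id). A
    candidate parent must be more abundant in total, at least
    ``min_similarity`` percent identical, present in at least
    ``min_cooccurrence`` of the daughter's samples, and more abundant by
    ``min_ratio`` (minimum or average of per-sample parent/daughter ratios
    over co-occurring samples). Among eligible parents the highest identity
    wins, ties by higher total count then asv_id. Counts are moved, never
    dropped; merge chains resolve transitively to the final survivors.
    """
    counts = table.counts.copy()
    seqs = table.sequences
    order = sorted(table.asv_ids,
                   key=lambda a: (int(table.total_counts()[a]), a))
    merged_into: dict[str, str] = {}
    active = set(table.asv_ids)

    sim_cache: dict[tuple[str, str], Fraction] = {}

    def similarity(d: str, p: str) -> Fraction:
        # pairs below the alignable-evidence floor count as 0% similar
        key = (d, p) if d < p else (p, d)
        if key not in sim_cache:
            st = pair_stats(seqs[key[0]], seqs[key[1]], scoring)
            sim_cache[key] = (Fraction(st.identical, st.denominator)
                              if st.denominator >= MIN_HIT_COLUMNS
                              else Fraction(0))
        return sim_cache[key]

    min_sim = Fraction(cfg.min_similarity).limit_denominator(10**6) / 100

    for d in order:
        if d not in active:
            continue
        drow = counts.loc[d]
        d_samples = drow[drow > 0].index
        if len(d_samples) == 0:
            continue
        d_total = int(drow.sum())
        best: tuple[Fraction, int, str] | None = None
        for p in active:
            if p == d:
                continue
            prow = counts.loc[p]
            p_total = int(prow.sum())
            if p_total <= d_total:
                continue
            co = [s for s in d_samples if prow[s] > 0]
            if Fraction(len(co), len(d_samples)) < Fraction(
                    cfg.min_cooccurrence).limit_denominator(10**6):
                continue
            sim = similarity(d, p)
            if sim < min_sim:
                continue
            ratios = [Fraction(int(prow[s]), int(drow[s])) for s in co]
            if not ratios:
                continue
            stat = min(ratios) if cfg.ratio_type == "min" else (
                sum(ratios) / len(ratios))
            if stat < Fraction(cfg.min_ratio).limit_denominator(10**6):
                continue
            cand = (sim, p_total, p)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                    (cand[0], cand[1]) == (best[0], best[1]) and p < best[2]):
                best = cand
        if best is not None:
            parent = best[2]
            counts.loc[parent] += counts.loc[d]
            counts.loc[d] = 0
            merged_into[d] = parent
            active.discard(d)

    # resolve chains: daughter of a daughter follows to the final survivor
    merge_map: dict[str, str] = {}
    for d in merged_into:
        p = merged_into[d]
        while p in merged_into:
            p = merged_into[p]
        merge_map[d] = p

    survivors = [a for a in table.asv_ids if a not in merge_map]
    curated = ASVTable(
        sequences={a: seqs[a] for a in survivors},
        counts=counts.loc[survivors],
    )
    return curated, merge_map


@dataclass
class AbundanceReport:
    """Per-sample relative abundances of assigned species plus a taxon tally."""

    relative_abundance: pd.DataFrame  # species x sample, fractions
    unassigned_fraction: pd.Series  # per sample
    taxon_tally: dict[str, int]
    empty_samples: list[str] = field(default_factory=list)


def abundance_report(
    table: ASVTable,
    assignments: Sequence[Assignment],
    lib: ReferenceLibrary,
) -> AbundanceReport:
    """Figure-style relative-abundance summary over the curated, assigned table.

    Relative abundance of a species in a sample = its assigned counts divided
    by the total assigned counts of that sample; samples with zero assigned
    counts are flagged rather than reported as zeros. The tally counts
    distinct species, genera, families and orders over all assigned ASVs.
    """
    by_asv = {a.asv_id: a for a in assignments}
    missing = set(table.asv_ids) - set(by_asv)
    if missing:
        raise ValueError(f"assignments missing for ASVs: {sorted(missing)}")
    assigned_ids = [a for a in table.asv_ids
                    if by_asv[a].status == "assigned"]
    species_of_asv = {a: by_asv[a].species for a in assigned_ids}

    rows: dict[str, pd.Series] = {}
    for asv_id in assigned_ids:
        sp = species_of_asv[asv_id]
        row = table.counts.loc[asv_id]
        rows[sp] = rows[sp].add(row, fill_value=0) if sp in rows else row.copy()
    species_counts = (pd.DataFrame(rows).T if rows else
                      pd.DataFrame(columns=table.sample_ids))
    species_counts = species_counts.reindex(columns=table.sample_ids,
                                            fill_value=0).sort_index()

    totals = table.counts.sum(axis=0)
    assigned_totals = species_counts.sum(axis=0)
    empty = [s for s in table.sample_ids if assigned_totals.get(s, 0) == 0]
    rel = species_counts.div(assigned_totals.replace(0, np.nan), axis=1)
    rel = rel.drop(columns=empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        unassigned = 1.0 - assigned_totals / totals.replace(0, np.nan)

    taxonomy: dict[str, tuple[str, str, str]] = {
        r.species: (r.genus, r.family, r.order) for r in lib.records
    }
    species = sorted({species_of_asv[a] for a in assigned_ids})
    tally = {
        "species": len(species),
        "genera": len({taxonomy[s][0] for s in species}),
        "families": len({taxonomy[s][1] for s in species}),
        "orders": len({taxonomy[s][2] for s in species}),
    }
    if empty:
        logger.warning("samples with zero assigned counts: %s", empty)
    return AbundanceReport(
        relative_abundance=rel,
        unassigned_fraction=unassigned,
        taxon_tally=tally,
        empty_samples=empty,
    )


# -- readers / writers -----------------------------------------------------

def read_asv_table(counts_tsv, fasta) -> ASVTable:
    """ASV table from a count TSV (asv_id + one column per sample) + FASTA."""
    from Bio import SeqIO

    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta), "fasta")}
    return ASVTable(sequences=seqs, counts=counts)


def write_asv_table(table: ASVTable, counts_tsv, fasta) -> None:
    table.counts.to_csv(counts_tsv, sep="\t", index_label="asv_id")
    with open(fasta, "w") as fh:
        for asv_id in table.asv_ids:
            fh.write(f">{asv_id}\n{table.sequences[asv_id]}\n")


def write_assignments(assignments: Iterable[Assignment], path) -> None:
    pd.DataFrame(
        [
            {
                "asv_id": a.asv_id,
                "status": a.status,
                "species": a.species if a.species is not None else "",
                "best_identity": a.best_identity,
                "best_coverage": a.best_coverage,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def write_merge_map(merge_map: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(merge_map.items()), columns=["daughter", "parent"]
    ).to_csv(path, sep="\t", index=False)
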
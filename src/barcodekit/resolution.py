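"""Best-match barcode resolution and the library-level summary statistics.

A query specimen is *correctly assigned* when its best identity hits point to
its own species: for a singleton species (no conspecific hit exists) no other
species may reach exactly 100% identity; for a multi-accession species the
best conspecific identity must be at least as high ("similar or higher",
tie_policy="pass", the default) or strictly higher (tie_policy="fail") than
the best heterospecific identity. All comparisons are exact rationals on
(identical, denominator) column counts -- never floats.

Species-level statuses aggregate over queries (default: every query must be
correct) into the summary block

    IS   correctly identified species          %IS  = 100*IS/(IS+NIS)
    NIS  nonidentified species                 %SS  = 100*(IS+NIS)/total
    NA   species with no available sequences
    SSA/SMA  species with one / more than one accession
    MS/NMS   supported-monophyletic / other multi-accession species
    %SMA = 100*SMA/(IS+NIS)    %MS = 100*MS/SMA

with percentages rounded half-up to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .library import ReferenceLibrary, reduced_library
from .pairwise import (
    AlignScoring,
    DEFAULT_SCORING,
    IdentityHit,
    all_pairs_combined,
    all_pairs_identity,
)

logger = logging.getLogger(__name__)

COMBINED = "combined"


def round2(num: int, den: int) -> float:
    """100*num/den rounded half-up to 2 decimals (the table rounding rule)."""
    if den == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = (Decimal(100 * num) / Decimal(den)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass(frozen=True)
class ResolutionConfig:
    """Policy knobs of the decision rule."""

    tie_policy: str = "pass"  # "pass": ties count as correct; "fail": strict
    aggregation: str = "all_queries"  # or "any_query"

    def __post_init__(self) -> None:
        if self.tie_policy not in ("pass", "fail"):
            raise ValueError("tie_policy must be 'pass' or 'fail'")
        if self.aggregation not in ("all_queries", "any_query"):
            raise ValueError("aggregation must be 'all_queries' or 'any_query'")


@dataclass(frozen=True)
class SpeciesStatus:
    species: str
    marker_scope: str
    status: str  # IS | NIS | NA
    n_accessions: int

    def __post_init__(self) -> None:
        if (self.status == "NA") != (self.n_accessions == 0):
            raise ValueError("status NA iff the species has no accessions")


@dataclass(frozen=True)
class ResolutionSummary:
    """One row of the resolution table; phylo block zeroed when absent."""

    IS: int
    NIS: int
    NA: int
    pct_IS: float | None
    pct_SS: float | None
    SSA: int = 0
    SMA: int = 0
    MS: int = 0
    NMS: int = 0
    pct_SMA: float | None = None
    pct_MS: float | None = None


def _best_pair_maxima(
    hits: Iterable[IdentityHit], species_of: Mapping[str, str]
) -> tuple[dict[str, Fraction], dict[str, Fraction], set[str]]:
    """Per-specimen max conspecific / heterospecific identity (as Fractions)
    and the set of specimens with a heterospecific exact-100 hit."""
    best_con: dict[str, Fraction] = {}
    best_het: dict[str, Fraction] = {}
    het100: set[str] = set()
    for h in hits:
        q, s = h.query_id, h.subject_id
        if q not in species_of or s not in species_of:
            continue
        ident = h.identity_fraction
        same = species_of[q] == species_of[s]
        for x in (q, s):
            d = best_con if same else best_het
            if x not in d or ident > d[x]:
                d[x] = ident
        if not same and h.identical == h.denominator and h.denominator > 0:
            het100.update((q, s))
    return best_con, best_het, het100


def query_correct(
    query: str,
    hits: Iterable[IdentityHit],
    species_of: Mapping[str, str],
    cfg: ResolutionConfig = ResolutionConfig(),
) -> bool:
    """Apply the correct-assignment rule to one query specimen.

    ``hits`` must contain every pair involving the query for the scope;
    ``species_of`` maps every in-scope specimen to its species.
    """
    if query not in species_of:
        raise KeyError(f"query {query!r} not among in-scope specimens")
    sp = species_of[query]
    multi = sum(1 for v in species_of.values() if v == sp) > 1
    involved = [h for h in hits
                if query in (h.query_id, h.subject_id)
                and h.query_id in species_of and h.subject_id in species_of]
    if multi and not any(
        species_of[h.query_id] == species_of[h.subject_id] == sp
        for h in involved
    ):
        raise ValueError(
            f"incomplete hit table: no conspecific hit for multi-accession "
            f"query {query!r}")
    best_con, best_het, het100 = _best_pair_maxima(involved, species_of)
    return _decide(query, best_con, best_het, het100, cfg)


def _decide(query, best_con, best_het, het100, cfg: ResolutionConfig) -> bool:
    if query not in best_con:  # singleton rule
        return query not in het100
    if query not in best_het:
        return True
    i, x = best_con[query], best_het[query]
    if i > x:
        return True
    return i == x and cfg.tie_policy == "pass"


def species_status(
    lib: ReferenceLibrary,
    hits: Sequence[IdentityHit],
    cfg: ResolutionConfig = ResolutionConfig(),
    scope: str | None = None,
    combo_markers: Sequence[str] | None = None,
    species_universe: Iterable[str] | None = None,
) -> list[SpeciesStatus]:
    """Status (IS / NIS / NA) of every species in scope.

    ``scope`` is a marker id or "combined" (inferred from the hits when
    omitted). For combined scope an accession is any specimen with at least
    one of ``combo_markers`` (default: all library markers). The species
    universe defaults to the library's species; pass the complete universe
    explicitly when scoring a reduced library so removed species count as NA.
    """
    if scope is None:
        if not hits:
            raise ValueError("cannot infer scope from an empty hit table")
        scope = hits[0].marker_scope
    if scope == COMBINED:
        markers = tuple(combo_markers) if combo_markers else lib.markers
        in_scope = {
            r.specimen_id: r.species
            for r in lib.records if r.marker_id in markers
        }
    else:
        in_scope = {
            r.specimen_id: r.species for r in lib.records_for_marker(scope)
        }
    universe = set(species_universe) if species_universe is not None \
        else lib.species
    n_acc: dict[str, int] = {}
    for sp in in_scope.values():
        n_acc[sp] = n_acc.get(sp, 0) + 1

    best_con, best_het, het100 = _best_pair_maxima(hits, in_scope)
    statuses: list[SpeciesStatus] = []
    queries_by_species: dict[str, list[str]] = {}
    for spm, sp in in_scope.items():
        queries_by_species.setdefault(sp, []).append(spm)
    for sp in sorted(universe | set(n_acc)):
        acc = n_acc.get(sp, 0)
        if acc == 0:
            statuses.append(SpeciesStatus(sp, scope, "NA", 0))
            continue
        verdicts = [
            _decide(q, best_con, best_het, het100, cfg)
            for q in sorted(queries_by_species[sp])
        ]
        ok = all(verdicts) if cfg.aggregation == "all_queries" else any(verdicts)
        statuses.append(SpeciesStatus(sp, scope, "IS" if ok else "NIS", acc))
    return statuses


def resolution_summary(
    statuses: Sequence[SpeciesStatus],
    phylo: tuple[int, int, int, int] | None = None,
) -> ResolutionSummary:
    """Counts and percentages from per-species statuses (+ optional phylo
    block (SSA, SMA, MS, NMS)). Conservation IS+NIS+NA = total is asserted;
    %MS is None (not 0) when SMA = 0."""
    IS = sum(1 for s in statuses if s.status == "IS")
    NIS = sum(1 for s in statuses if s.status == "NIS")
    NA = sum(1 for s in statuses if s.status == "NA")
    if IS + NIS + NA != len(statuses):
        raise AssertionError("species statuses are not a partition")
    return summary_from_counts(IS, NIS, NA, phylo)


def summary_from_counts(
    IS: int, NIS: int, NA: int,
    phylo: tuple[int, int, int, int] | None = None,
) -> ResolutionSummary:
    """Summary row from raw count cells (also the entry point for published
    count blocks)."""
    with_seq = IS + NIS
    total = with_seq + NA
    pct_IS = round2(IS, with_seq) if with_seq else None
    pct_SS = round2(with_seq, total) if total else None
    if phylo is None:
        return ResolutionSummary(IS, NIS, NA, pct_IS, pct_SS)
    SSA, SMA, MS, NMS = phylo
    if MS + NMS != SMA:
        raise ValueError("phylo block violates MS + NMS = SMA")
    if SSA + SMA != with_seq:
        raise ValueError("phylo block violates SSA + SMA = IS + NIS")
    pct_SMA = round2(SMA, with_seq) if with_seq else None
    pct_MS = round2(MS, SMA) if SMA else None
    return ResolutionSummary(IS, NIS, NA, pct_IS, pct_SS,
                             SSA, SMA, MS, NMS, pct_SMA, pct_MS)


def novelty_report(
    lib_species: Iterable[str], external_species: Iterable[str]
) -> tuple[int, int]:
    """(n_new, n_known) of library species against an external checklist."""
    lib_set, ext = set(lib_species), set(external_species)
    n_new = len(lib_set - ext)
    return n_new, len(lib_set) - n_new


def six_matrix_statuses(
    lib: ReferenceLibrary,
    markers: Sequence[str] | None = None,
    cfg: ResolutionConfig = ResolutionConfig(),
    scoring: AlignScoring = DEFAULT_SCORING,
) -> dict[str, list[SpeciesStatus]]:
    """Per-species statuses for the six scopes: each marker, the combination,
    each under complete and reduced sampling (reduced = species with every
    marker). Keys: "<marker>", "<marker>_reduced", "combined",
    "combined_reduced"."""
    markers = tuple(markers) if markers is not None else lib.markers
    universe = lib.species
    per_marker_hits = {m: all_pairs_identity(lib, m, scoring) for m in markers}
    combined_hits = all_pairs_combined(lib, markers, scoring, per_marker_hits)
    red = reduced_library(lib, set(markers))
    red_specimens = red.specimens

    def restrict(hits):
        return [h for h in hits
                if h.query_id in red_specimens and h.subject_id in red_specimens]

    out: dict[str, list[SpeciesStatus]] = {}
    for m in markers:
        out[m] = species_status(
            lib, per_marker_hits[m], cfg, scope=m, species_universe=universe)
        out[f"{m}_reduced"] = species_status(
            red, restrict(per_marker_hits[m]), cfg, scope=m,
            species_universe=universe)
    out[COMBINED] = species_status(
        lib, combined_hits, cfg, scope=COMBINED, combo_markers=markers,
        species_universe=universe)
    out[f"{COMBINED}_reduced"] = species_status(
        red, restrict(combined_hits), cfg, scope=COMBINED,
        combo_markers=markers, species_universe=universe)
    return out


def statuses_to_frame(
    statuses_by_scope: Mapping[str, Sequence[SpeciesStatus]]
) -> pd.DataFrame:
    rows = [
        {"scope": scope, "species": s.species, "status": s.status,
         "n_accessions": s.n_accessions}
        for scope, statuses in statuses_by_scope.items()
        for s in statuses
    ]
    return pd.DataFrame(rows,
                        columns=["scope", "species", "status", "n_accessions"])


def summaries_to_frame(
    summaries: Mapping[str, ResolutionSummary]
) -> pd.DataFrame:
    """Summary rows in the published table's column order."""
    rows = []
    for scope, s in summaries.items():
        rows.append({
            "Marker": scope, "IS": s.IS, "NIS": s.NIS, "NA": s.NA,
            "%IS": s.pct_IS, "%SS": s.pct_SS, "SSA": s.SSA, "SMA": s.SMA,
            "MS": s.MS, "NMS": s.NMS, "%SMA": s.pct_SMA, "%MS": s.pct_MS,
        })
    return pd.DataFrame(rows, columns=[
        "Marker", "IS", "NIS", "NA", "%IS", "%SS", "SSA", "SMA", "MS", "NMS",
        "%SMA", "%MS"])
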
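"""Synthetic reference libraries and bulk-sample ASV tables with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not sequencing realism: a ranked taxonomy with a singleton-rich
species abundance pattern (most species sampled once), two markers with
contrasting substitution rates (a slow plastid-like gene and a fast nuclear
spacer), per-record missingness, and plot-structured bulk samples whose true
ASVs can spawn low-abundance erroneous daughters.

Sequences evolve under Jukes-Cantor along the rank hierarchy
(family -> genus -> species -> specimen): across a total branch length d the
probability a site differs from its ancestor is (3/4)(1 - exp(-4d/3)), which
gives every test a closed-form identity expectation. Indels (single-site
deletions, inherited by descendants) are applied only to the fast marker, so
its raw sequences vary in length while every marker also has an exactly
aligned matrix available for tree building.

Every generator is a pure function of its config: one seeded stream per
operation, consumed in a fixed documented order
(taxonomy -> sequences -> missingness -> plots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library import BarcodeRecord, ReferenceLibrary, write_library
from .metabarcoding import ASVTable

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

IntOrRange = int | tuple[int, int]


@dataclass(frozen=True)
class MarkerProfile:
    """Evolutionary profile of one marker.

    rate_multiplier scales every divergence; indel_rate is the per-site
    deletion probability per branch; missing_prob is the chance a specimen
    lacks this marker entirely.
    """

    marker_id: str
    base_length: int
    rate_multiplier: float = 1.0
    indel_rate: float = 0.0
    missing_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.base_length <= 0:
            raise ValueError("base_length must be positive")
        if not 0 <= self.missing_prob <= 1:
            raise ValueError("missing_prob must lie in [0, 1]")
        if self.rate_multiplier <= 0 or self.indel_rate < 0:
            raise ValueError("rates must be positive / nonnegative")


#: Default marker pair: a slow, long plastid-like gene and a fast nuclear
#: spacer-like region (smaller amplicon, ~5x substitution rate, rare
#: single-site deletions). Missingness ~0.12 per record leaves roughly three
#: quarters of species with both markers.
DEFAULT_MARKERS = (
    MarkerProfile("rbcL-like", base_length=550, rate_multiplier=1.0,
                  indel_rate=0.0, missing_prob=0.12),
    MarkerProfile("ITS2-like", base_length=450, rate_multiplier=5.0,
                  indel_rate=0.002, missing_prob=0.12),
)

#: Expected substitutions/site at rate_multiplier 1 for each rank's branch.
DEFAULT_DIVERGENCE = {
    "family": 0.15,
    "genus": 0.08,
    "species": 0.04,
    "intraspecific": 0.003,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and depth of the synthetic reference library.

    Defaults target roughly a hundred species with the singleton share of the
    emulated field collections (0.62) and strongly separated species
    (species-level divergence an order of magnitude above intraspecific).
    """

    n_families: IntOrRange = 25
    genera_per_family: IntOrRange = (1, 3)
    species_per_genus: IntOrRange = (1, 3)
    families_per_order: IntOrRange = 2
    singleton_fraction: float = 0.62
    specimens_per_species_range: tuple[int, int] = (2, 3)
    divergence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE))
    markers: tuple[MarkerProfile, ...] = DEFAULT_MARKERS
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.divergence
        ranks = ("family", "genus", "species", "intraspecific")
        if set(d) != set(ranks):
            raise ValueError(f"divergence must give exactly the ranks {ranks}")
        vals = [d[r] for r in ranks]
        if any(v < 0 for v in vals):
            raise ValueError("divergences must be nonnegative")
        if not (vals[0] >= vals[1] >= vals[2] >= vals[3]):
            raise ValueError(
                "divergence must be ordered family >= genus >= species "
                ">= intraspecific")
        if not 0 <= self.singleton_fraction <= 1:
            raise ValueError("singleton_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class BulkConfig:
    """Plot-structured bulk samples drawn from the reference library."""

    n_plots: int = 6
    species_per_plot: tuple[int, int] = (8, 15)
    abundance_lognormal_sigma: float = 1.0
    median_reads: int = 300
    error_asv_prob: float = 0.3
    error_substitutions: int = 2
    error_abundance_ratio: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.error_abundance_ratio < 1:
            raise ValueError("error_abundance_ratio must lie in (0, 1)")
        if self.n_plots <= 0:
            raise ValueError("n_plots must be positive")


@dataclass
class TruthTable:
    """Ground truth emitted alongside each synthetic artefact."""

    record_species: dict[str, str] = field(default_factory=dict)
    aligned: dict[str, dict[str, str]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    asv_truth: pd.DataFrame | None = None
    plot_species: dict[str, list[str]] = field(default_factory=dict)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _draw(rng: np.random.Generator, value: IntOrRange) -> int:
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def simulate_taxonomy(cfg: SimulationConfig) -> pd.DataFrame:
    """Ranked taxonomy + specimen list, one row per specimen.

    Species are singletons with probability singleton_fraction, otherwise
    their specimen count is uniform on specimens_per_species_range.
    """
    rng = _rng(cfg.seed, 0)
    n_fam = _draw(rng, cfg.n_families)
    if n_fam <= 0:
        raise ValueError("need at least one family")
    rows = []
    spm = 0
    species_counter = 0
    fams_per_order = max(1, _draw(rng, cfg.families_per_order))
    for fi in range(n_fam):
        family = f"fam{fi + 1:03d}"
        order = f"ord{fi // fams_per_order + 1:03d}"
        n_gen = _draw(rng, cfg.genera_per_family)
        if n_gen <= 0:
            raise ValueError("need at least one genus per family")
        for gi in range(n_gen):
            genus = f"gen{fi + 1:03d}.{gi + 1:02d}"
            n_sp = _draw(rng, cfg.species_per_genus)
            if n_sp <= 0:
                raise ValueError("need at least one species per genus")
            for si in range(n_sp):
                species_counter += 1
                species = f"{genus} sp{si + 1:02d}"
                if rng.random() < cfg.singleton_fraction:
                    n_spm = 1
                else:
                    lo, hi = cfg.specimens_per_species_range
                    n_spm = int(rng.integers(lo, hi + 1))
                for _ in range(n_spm):
                    spm += 1
                    rows.append((f"SPM{spm:05d}", species, genus, family, order))
    if species_counter == 0:
        raise ValueError("simulated taxonomy has no species")
    return pd.DataFrame(
        rows, columns=["specimen_id", "species", "genus", "family", "order"]
    )


def _jc_evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch: P(site changes) = (3/4)(1 - exp(-4d/3))."""
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    mask = rng.random(seq.shape[0]) < p
    out = seq.copy()
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, size=k)) % 4
    return out


def simulate_sequences(
    taxonomy: pd.DataFrame, cfg: SimulationConfig
) -> tuple[ReferenceLibrary, TruthTable]:
    """Evolve one root per marker down the rank hierarchy; apply missingness.

    Returns the library (raw sequences, deletions removed) and a truth table
    carrying the per-marker aligned matrices (gaps at deleted sites) and the
    generator's own counts.
    """
    rng = _rng(cfg.seed, 1)
    div = cfg.divergence
    groups = taxonomy.groupby(["family", "genus", "species"], sort=True)
    lineage: list[tuple[str, str, str, list[str]]] = [
        (fam, gen, sp, sorted(sub["specimen_id"]))
        for (fam, gen, sp), sub in groups
    ]

    aligned: dict[str, dict[str, str]] = {}
    raw: dict[str, dict[str, str]] = {}
    for prof in cfg.markers:
        L = prof.base_length
        root = rng.integers(0, 4, size=L)
        m_aligned: dict[str, str] = {}
        fam_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        gen_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        sp_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        def step(seq, dele, d_rank):
            d = d_rank * prof.rate_multiplier
            nxt = _jc_evolve(seq, d, rng)
            new_del = dele | (rng.random(L) < prof.indel_rate)
            return nxt, new_del

        nodel = np.zeros(L, dtype=bool)
        for fam, gen, sp, specimens in lineage:
            if fam not in fam_state:
                fam_state[fam] = step(root, nodel, div["family"])
            if gen not in gen_state:
                gen_state[gen] = step(*fam_state[fam], div["genus"])
            if sp not in sp_state:
                sp_state[sp] = step(*gen_state[gen], div["species"])
            for spm in specimens:
                seq, dele = step(*sp_state[sp], div["intraspecific"])
                chars = _BASES[seq].copy()
                chars[dele] = "-"
                m_aligned[spm] = "".join(chars)
        aligned[prof.marker_id] = m_aligned
        raw[prof.marker_id] = {
            spm: s.replace("-", "") for spm, s in m_aligned.items()
        }

    miss_rng = _rng(cfg.seed, 2)
    tax_of = {
        r.specimen_id: r for r in taxonomy.itertuples(index=False)
    }
    records: list[BarcodeRecord] = []
    per_marker_n: dict[str, int] = {}
    for prof in cfg.markers:
        n = 0
        for spm in sorted(raw[prof.marker_id]):
            if miss_rng.random() < prof.missing_prob:
                continue
            row = tax_of[spm]
            records.append(BarcodeRecord(
                specimen_id=spm, marker_id=prof.marker_id,
                sequence=raw[prof.marker_id][spm],
                species=row.species, genus=row.genus,
                family=row.family, order=row.order,
            ))
            n += 1
        per_marker_n[prof.marker_id] = n

    lib = ReferenceLibrary(
        records=records, markers=tuple(p.marker_id for p in cfg.markers)
    )
    truth = TruthTable(
        record_species=dict(zip(taxonomy["specimen_id"], taxonomy["species"])),
        aligned=aligned,
        counts={
            "n_specimens": len(lib.specimens),
            "n_species": len(lib.species),
            "n_barcodes": len(records),
            **{f"n_records_{m}": n for m, n in per_marker_n.items()},
        },
    )
    return lib, truth


def simulate_library(cfg: SimulationConfig) -> tuple[ReferenceLibrary, TruthTable]:
    """Taxonomy + sequences in one call."""
    return simulate_sequences(simulate_taxonomy(cfg), cfg)


def simulate_bulk_samples(
    lib: ReferenceLibrary,
    cfg: BulkConfig,
    marker: str | None = None,
) -> tuple[ASVTable, TruthTable]:
    """Plot-structured bulk samples with true and erroneous ASVs.

    Per plot a species subset is drawn without replacement among species with
    the fast (default: last) marker; a species lacking it is never sampled and
    is logged. Each sampled species contributes the fast-marker sequence of
    one of its specimens with a lognormal read count (min 1). A true ASV
    spawns, with probability error_asv_prob, a daughter differing by
    error_substitutions substitutions, present only where the parent is, at
    round(parent count x error_abundance_ratio) reads.
    """
    marker = marker if marker is not None else lib.markers[-1]
    rng = _rng(cfg.seed, 3)
    by_species: dict[str, list[BarcodeRecord]] = {}
    for rec in sorted(lib.records_for_marker(marker),
                      key=lambda r: r.specimen_id):
        by_species.setdefault(rec.species, []).append(rec)
    skipped = sorted(lib.species - set(by_species))
    if skipped:
        logger.warning(
            "%d species lack marker %s and cannot appear in bulk samples: %s",
            len(skipped), marker, skipped[:5])
    pool = sorted(by_species)
    if not pool:
        raise ValueError(f"no species with marker {marker!r}")

    plots = [f"plot{i + 1}" for i in range(cfg.n_plots)]
    seq_counts: dict[str, dict[str, int]] = {}
    seq_species: dict[str, str] = {}
    plot_species: dict[str, list[str]] = {}
    mu = np.log(cfg.median_reads)
    for plot in plots:
        lo, hi = cfg.species_per_plot
        k = min(int(rng.integers(lo, hi + 1)), len(pool))
        chosen = sorted(rng.choice(len(pool), size=k, replace=False))
        plot_species[plot] = [pool[i] for i in chosen]
        for sp in plot_species[plot]:
            recs = by_species[sp]
            rec = recs[int(rng.integers(0, len(recs)))]
            count = max(1, int(round(float(rng.lognormal(
                mean=mu, sigma=cfg.abundance_lognormal_sigma)))))
            seq_counts.setdefault(rec.sequence, {})
            seq_counts[rec.sequence][plot] = (
                seq_counts[rec.sequence].get(plot, 0) + count)
            seq_species.setdefault(rec.sequence, rec.species)

    # stable ids: true ASVs ordered by descending total count then sequence
    true_seqs = sorted(
        seq_counts, key=lambda s: (-sum(seq_counts[s].values()), s))
    sequences: dict[str, str] = {}
    counts_rows: dict[str, dict[str, int]] = {}
    truth_rows: list[dict] = []
    for i, s in enumerate(true_seqs):
        asv = f"asv{i + 1:04d}"
        sequences[asv] = s
        counts_rows[asv] = seq_counts[s]
        truth_rows.append({
            "asv_id": asv, "species": seq_species[s],
            "erroneous": False, "parent_asv": "",
        })

    existing = set(true_seqs)
    n_err = 0
    for i, s in enumerate(true_seqs):
        if rng.random() >= cfg.error_asv_prob:
            continue
        parent_asv = f"asv{i + 1:04d}"
        for _ in range(20):  # avoid colliding with an existing sequence
            arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
            pos = rng.choice(len(s), size=min(cfg.error_substitutions, len(s)),
                             replace=False)
            for p in pos:
                cur = chr(arr[p])
                alts = [b for b in "ACGT" if b != cur]
                arr[p] = ord(alts[int(rng.integers(0, len(alts)))])
            daughter = arr.tobytes().decode()
            if daughter not in existing:
                break
        else:  # pragma: no cover - vanishingly unlikely
            continue
        drow = {
            plot: int(round(c * cfg.error_abundance_ratio))
            for plot, c in counts_rows[parent_asv].items()
        }
        drow = {p: c for p, c in drow.items() if c > 0}
        if not drow:
            logger.info("erroneous daughter of %s rounded to zero reads",
                        parent_asv)
            continue
        n_err += 1
        asv = f"asv{len(true_seqs) + n_err:04d}"
        existing.add(daughter)
        sequences[asv] = daughter
        counts_rows[asv] = drow
        truth_rows.append({
            "asv_id": asv, "species": seq_species[s],
            "erroneous": True, "parent_asv": parent_asv,
        })

    counts = pd.DataFrame(
        [[counts_rows[a].get(p, 0) for p in plots] for a in sequences],
        index=list(sequences), columns=plots, dtype=np.int64,
    )
    table = ASVTable(sequences=sequences, counts=counts)
    truth = TruthTable(
        asv_truth=pd.DataFrame(
            truth_rows,
            columns=["asv_id", "species", "erroneous", "parent_asv"]),
        plot_species={p: sorted(sp) for p, sp in plot_species.items()},
    )
    return table, truth


def plant_identical_species_pairs(
    lib: ReferenceLibrary, k: int
) -> tuple[ReferenceLibrary, list[tuple[str, str]]]:
    """Overwrite k species' sequences with those of k other species.

    Selects, deterministically, 2k species having at least one record of
    every marker; pairs them (1st with 2nd, ...) and replaces every record of
    the second species by the corresponding (cycled) sequence of the first,
    per marker. Each planted pair then shares an identical sequence set, so
    neither member can be discriminated: a ground-truth fixture for the
    strict tie policy of the resolution rule.
    """
    per_marker_species: dict[str, set[str]] = {}
    for rec in lib.records:
        per_marker_species.setdefault(rec.marker_id, set()).add(rec.species)
    eligible = sorted(set.intersection(*per_marker_species.values()))
    if len(eligible) < 2 * k:
        raise ValueError(
            f"need {2 * k} species with all markers, found {len(eligible)}")
    pairs = [(eligible[2 * i], eligible[2 * i + 1]) for i in range(k)]
    donor_of = {b: a for a, b in pairs}

    donor_seqs: dict[tuple[str, str], list[str]] = {}
    for rec in sorted(lib.records, key=lambda r: (r.specimen_id, r.marker_id)):
        if rec.species in donor_of.values():
            donor_seqs.setdefault((rec.species, rec.marker_id),
                                  []).append(rec.sequence)

    new_records = []
    counters: dict[tuple[str, str], int] = {}
    for rec in lib.records:
        if rec.species in donor_of:
            donor = donor_of[rec.species]
            seqs = donor_seqs.get((donor, rec.marker_id))
            if seqs:
                i = counters.get((rec.species, rec.marker_id), 0)
                counters[(rec.species, rec.marker_id)] = i + 1
                rec = replace(rec, sequence=seqs[i % len(seqs)])
        new_records.append(rec)
    return ReferenceLibrary(records=new_records, markers=lib.markers), pairs


def write_truth(truth: TruthTable, out_dir: str | Path,
                prefix: str = "truth") -> dict[str, Path]:
    """TSV dumps of whichever truth blocks are populated."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if truth.record_species:
        p = out_dir / f"{prefix}_record_species.tsv"
        pd.DataFrame(
            sorted(truth.record_species.items()),
            columns=["specimen_id", "species"],
        ).to_csv(p, sep="\t", index=False)
        written["record_species"] = p
    if truth.asv_truth is not None:
        p = out_dir / f"{prefix}_asv.tsv"
        truth.asv_truth.to_csv(p, sep="\t", index=False)
        written["asv"] = p
    if truth.plot_species:
        p = out_dir / f"{prefix}_plot_species.tsv"
        rows = [
            {"plot": plot, "species": sp}
            for plot in sorted(truth.plot_species)
            for sp in truth.plot_species[plot]
        ]
        pd.DataFrame(rows, columns=["plot", "species"]).to_csv(
            p, sep="\t", index=False)
        written["plot_species"] = p
    return written


def write_simulated_library(
    lib: ReferenceLibrary, truth: TruthTable, out_dir: str | Path
) -> dict[str, Path]:
    written = write_library(lib, out_dir, prefix="library")
    written.update(write_truth(truth, out_dir, prefix="truth"))
    return written
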
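"""ASV assignment, co-occurrence curation and the abundance report."""

import numpy as np
import pandas as pd
import pytest

from barcodekit import (
    ASVTable,
    AssignmentConfig,
    CurationConfig,
    abundance_report,
    assign_asvs,
    curate,
)
from barcodekit.metabarcoding import read_asv_table, write_asv_table


def _table(rows: dict[str, tuple[str, list[int]]], samples=None) -> ASVTable:
    samples = samples or [f"s{i + 1}" for i in
                          range(len(next(iter(rows.values()))[1]))]
    return ASVTable(
        sequences={a: seq for a, (seq, _) in rows.items()},
        counts=pd.DataFrame(
            {a: counts for a, (_, counts) in rows.items()},
            index=samples).T,
    )


BASE = "ACGTACGTTGCAACGGTTCAGATCAGGATCCAATGGTCCA"


def _mut(s, *pos):
    out = list(s)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestAssign:
    def test_exact_match_assigned_at_100(self, tiny_library):
        t = _table({"asv1": (tiny_library.sequence("a1", "m1"), [5, 0])})
        (a,) = assign_asvs(t, tiny_library, AssignmentConfig(marker="m1"))
        assert a.status == "assigned"
        assert a.species == "speciesA"
        assert a.best_identity == 100.0

    def test_below_identity_threshold(self, tiny_library):
        seq = _mut(tiny_library.sequence("c1", "m1"),
                   *range(0, 12))  # 12 of 40 sites changed: 70% identity
        t = _table({"asv1": (seq, [5])}, samples=["s1"])
        (a,) = assign_asvs(t, tiny_library, AssignmentConfig(marker="m1"))
        assert a.status == "below_threshold"
        assert a.species is None

    def test_equidistant_between_species_is_ambiguous(self):
        from barcodekit import BarcodeRecord, ReferenceLibrary

        x = BASE
        y = _mut(BASE, 0)  # asv differs from both refs by the same 1 site
        asv = _mut(BASE, 20)
        lib = ReferenceLibrary(
            records=[
                BarcodeRecord("r1", "m1", _mut(x, 20, 0), "spX", "g", "f", "o"),
                BarcodeRecord("r2", "m1", _mut(y, 20, 0), "spY", "g", "f", "o"),
            ],
            markers=("m1",),
        )
        # place asv equally distant from both references
        t = _table({"asv1": (_mut(BASE, 20), [3])}, samples=["s1"])
        res = assign_asvs(t, lib, AssignmentConfig(marker="m1",
                                                   min_identity=90))
        assert res[0].status == "ambiguous"

    def test_reference_sequences_assign_to_own_species(self, tiny_library):
        rows = {
            f"asv{i}": (r.sequence, [1])
            for i, r in enumerate(tiny_library.records_for_marker("m1"))
        }
        t = _table(rows, samples=["s1"])
        recs = tiny_library.records_for_marker("m1")
        res = assign_asvs(t, tiny_library, AssignmentConfig(marker="m1"))
        for a, rec in zip(res, recs):
            assert a.status == "assigned"
            assert a.species == rec.species
            assert a.best_identity == 100.0

    def test_empty_marker_fatal(self, tiny_library):
        t = _table({"asv1": (BASE, [1])}, samples=["s1"])
        with pytest.raises(ValueError, match="marker"):
            assign_asvs(t, tiny_library, AssignmentConfig(marker="nope"))


class TestCurate:
    def test_injected_daughter_merged(self):
        parent = BASE
        daughter = _mut(BASE, 3, 17)
        t = _table({
            "parent": (parent, [100, 50, 0]),
            "dau": (daughter, [10, 5, 0]),
            "other": (_mut(BASE, *range(0, 30, 2)), [40, 0, 30]),
        })
        curated, mm = curate(t)
        assert mm == {"dau": "parent"}
        assert list(curated.counts.loc["parent"]) == [110, 55, 0]

    def test_low_similarity_candidate_retained(self):
        far = _mut(BASE, *range(0, 21, 3))  # 7 subs: 82.5% < 84
        t = _table({"big": (BASE, [100]), "small": (far, [10])},
                   samples=["s1"])
        curated, mm = curate(t)
        assert mm == {}
        assert set(curated.asv_ids) == {"big", "small"}

    def test_low_cooccurrence_retained(self):
        t = _table({
            "big": (BASE, [100, 100, 0, 0]),
            "small": (_mut(BASE, 1), [5, 0, 5, 5]),  # 1/3 of its samples
        })
        curated, mm = curate(t)
        assert mm == {}

    def test_reads_conserved_per_sample(self, sim_bulk):
        table, _ = sim_bulk
        curated, _ = curate(table)
        assert (curated.counts.sum(axis=0) == table.counts.sum(axis=0)).all()

    def test_merge_chain_resolves_to_final_survivor(self):
        a = BASE
        b = _mut(BASE, 0)
        c = _mut(BASE, 0, 1)
        t = _table({
            "a": (a, [1000]),
            "b": (b, [100]),
            "c": (c, [10]),
        }, samples=["s1"])
        curated, mm = curate(t)
        assert set(curated.asv_ids) == {"a"}
        assert mm["c"] in ("a",)  # chains point at the survivor
        assert mm["b"] == "a"
        assert curated.counts.loc["a", "s1"] == 1110

    def test_monotone_in_similarity_threshold(self, sim_bulk):
        table, _ = sim_bulk
        merged = [
            len(curate(table, CurationConfig(min_similarity=s))[1])
            for s in (84.0, 95.0, 99.9)
        ]
        assert merged == sorted(merged, reverse=True)

    def test_fixed_point_no_remaining_mergeable_pair(self, sim_bulk):
        table, _ = sim_bulk
        curated, _ = curate(table)
        again, mm2 = curate(curated)
        assert mm2 == {}

    def test_curation_recovers_truth_exactly(self, curated_run):
        table, truth, curated, merge_map, _ = curated_run
        err = set(truth.asv_truth.loc[truth.asv_truth.erroneous, "asv_id"])
        assert set(merge_map) == err
        true_ids = set(truth.asv_truth.loc[~truth.asv_truth.erroneous,
                                           "asv_id"])
        assert set(curated.asv_ids) == true_ids


class TestAbundance:
    def test_single_species_sample_has_share_1(self, tiny_library):
        t = _table({"asv1": (tiny_library.sequence("a1", "m1"), [7])},
                   samples=["s1"])
        asg = assign_asvs(t, tiny_library, AssignmentConfig(marker="m1"))
        rep = abundance_report(t, asg, tiny_library)
        assert rep.relative_abundance.loc["speciesA", "s1"] == 1.0

    def test_shares_sum_to_one_per_sample(self, curated_run, sim_library):
        lib, _ = sim_library
        _, _, curated, _, assignments = curated_run
        rep = abundance_report(curated, assignments, lib)
        sums = rep.relative_abundance.sum(axis=0)
        assert np.allclose(sums.to_numpy(), 1.0)

    def test_plot_species_lists_recovered(self, curated_run, sim_library):
        lib, _ = sim_library
        table, truth, curated, _, assignments = curated_run
        sp_of = {a.asv_id: a.species for a in assignments
                 if a.status == "assigned"}
        for plot in table.sample_ids:
            got = sorted({
                sp_of[a] for a in curated.asv_ids
                if curated.counts.loc[a, plot] > 0 and a in sp_of
            })
            assert got == truth.plot_species[plot]

    def test_empty_sample_flagged_not_zeroed(self, tiny_library):
        t = _table({"asv1": (tiny_library.sequence("a1", "m1"), [7, 0])},
                   samples=["s1", "s2"])
        asg = assign_asvs(t, tiny_library, AssignmentConfig(marker="m1"))
        rep = abundance_report(t, asg, tiny_library)
        assert rep.empty_samples == ["s2"]
        assert "s2" not in rep.relative_abundance.columns


class TestASVIO:
    def test_round_trip(self, tmp_path, sim_bulk):
        table, _ = sim_bulk
        write_asv_table(table, tmp_path / "c.tsv", tmp_path / "s.fasta")
        back = read_asv_table(tmp_path / "c.tsv", tmp_path / "s.fasta")
        assert back.sequences == table.sequences
        assert back.counts.equals(table.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ASVTable(sequences={"a": "ACGT"},
                     counts=pd.DataFrame({"s1": [-1]}, index=["a"]))

    def test_row_without_sequence_rejected(self):
        with pytest.raises(ValueError, match="without a sequence"):
            ASVTable(sequences={},
                     counts=pd.DataFrame({"s1": [1]}, index=["a"]))
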
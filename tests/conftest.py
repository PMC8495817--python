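"""Shared fixtures: a tiny hand-built library and one session-scoped run of
the full synthetic pipeline (library, six-scope resolution, bulk samples)
that several test modules inspect from different angles."""

from __future__ import annotations

import logging

import pytest
from hypothesis import HealthCheck, settings

from barcodekit import (
    BarcodeRecord,
    BulkConfig,
    ReferenceLibrary,
    SimulationConfig,
    simulate_bulk_samples,
    simulate_library,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("barcodekit").setLevel(logging.ERROR)

#: seed of the session-wide synthetic run
SEED = 7


def _rec(spm, marker, seq, species, genus="gA", family="fA", order="oA"):
    return BarcodeRecord(
        specimen_id=spm, marker_id=marker, sequence=seq,
        species=species, genus=genus, family=family, order=order,
    )


@pytest.fixture()
def tiny_library() -> ReferenceLibrary:
    """Four species, two markers, 40 nt alignable sequences; speciesD is a
    singleton lacking the second marker."""
    base = "ACGTACGTTGCAACGGTTCAGATCAGGATCCAATGGTCCA"
    mut = lambda s, i, c: s[:i] + c + s[i + 1:]  # noqa: E731
    a1 = base
    a2 = mut(base, 5, "T")                      # 1 diff from a1
    b1 = mut(mut(base, 10, "A"), 20, "T")       # 2 diffs
    b2 = mut(mut(base, 10, "A"), 21, "C")
    c1 = mut(mut(mut(base, 2, "G"), 15, "C"), 30, "T")
    d1 = mut(mut(mut(mut(base, 3, "A"), 12, "G"), 22, "A"), 33, "G")
    m2 = base[::-1]
    records = [
        _rec("a1", "m1", a1, "speciesA"),
        _rec("a2", "m1", a2, "speciesA"),
        _rec("b1", "m1", b1, "speciesB", genus="gB"),
        _rec("b2", "m1", b2, "speciesB", genus="gB"),
        _rec("c1", "m1", c1, "speciesC", genus="gB"),
        _rec("d1", "m1", d1, "speciesD", genus="gC", family="fB", order="oB"),
        _rec("a1", "m2", m2, "speciesA"),
        _rec("a2", "m2", mut(m2, 7, "A"), "speciesA"),
        _rec("b1", "m2", mut(m2, 18, "C"), "speciesB", genus="gB"),
        _rec("b2", "m2", mut(m2, 19, "T"), "speciesB", genus="gB"),
        _rec("c1", "m2", mut(mut(m2, 4, "T"), 25, "G"), "speciesC",
             genus="gB"),
    ]
    return ReferenceLibrary(records=records, markers=("m1", "m2"))


@pytest.fixture(scope="session")
def sim_library():
    """The default-condition synthetic library (about a hundred species,
    singleton-rich, two contrasting markers)."""
    return simulate_library(SimulationConfig(seed=SEED))


@pytest.fixture(scope="session")
def sim_bulk(sim_library):
    lib, _ = sim_library
    return simulate_bulk_samples(lib, BulkConfig(seed=SEED))


@pytest.fixture(scope="session")
def six_matrix(sim_library):
    """Statuses of the six scopes on the session library (the expensive
    all-to-all alignment run, shared across modules)."""
    from barcodekit import six_matrix_statuses

    lib, _ = sim_library
    return six_matrix_statuses(lib)


@pytest.fixture(scope="session")
def curated_run(sim_library, sim_bulk):
    """Curation + assignment on the session bulk samples."""
    from barcodekit import AssignmentConfig, assign_asvs, curate

    lib, _ = sim_library
    table, truth = sim_bulk
    curated, merge_map = curate(table)
    assignments = assign_asvs(
        curated, lib, AssignmentConfig(marker=lib.markers[-1]))
    return table, truth, curated, merge_map, assignments
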
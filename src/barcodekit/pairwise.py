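"""Semi-global pairwise alignment, percent identity and query coverage.

This is the search primitive behind both the reference-library resolution rule
and the metabarcoding assignment stage. Alignments are optimal semi-global
(terminal gaps free) affine-gap alignments computed by full dynamic
programming -- library sizes here are desk-scale, and exactness beats speed.

Definitions
-----------
identity
    100 x identical columns / columns of the alignment excluding columns where
    either row has a terminal gap. Internal gap columns count in the
    denominator. An ambiguity code is identical only to the exact same symbol.
coverage
    100 x query residues inside the non-terminal-gap region / query length.
    Identity is symmetric in query and subject; coverage is not.

A gap of length g costs ``gap_open + g * gap_extend`` (open charged once,
extend per gap column). Among equal-score alignments the one with fewer gap
columns is preferred, then the one placing gaps leftmost (operationally:
backward traceback prefers substitution over a gap in the subject over a gap
in the query).

Decision rules downstream never compare floating identities: every hit
carries the exact (identical, denominator) integer pair.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numba
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum aligned (non-terminal) columns for a comparison to count as a hit.
#: Deeply diverged sequences (a fast spacer across families is effectively
#: unalignable) optimally align as a tiny chance overlap under semi-global
#: scoring; a BLAST-style evidence floor keeps such spurious near-100%
#: micro-hits out of the hit tables, as word-size/E-value cutoffs do in a
#: real search. Full-length barcode comparisons are never affected.
MIN_HIT_COLUMNS = 30

_SCALE = np.int32(1 << 12)  # score quantum; must exceed any gap-column count
_NEG = np.int32(-(1 << 29))
_MAX_LEN = 2000  # keeps n+m below _SCALE and scores inside int32

_CODES = "ACGTRYSWKMBDHVN"
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_CODES):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC DNA string as uint8 codes; unknown symbols are fatal."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(arr == 255)[0]})
        raise ValueError(f"non-IUPAC symbols in sequence: {bad}")
    return arr


@dataclass(frozen=True)
class AlignScoring:
    """blastn-like scoring for the semi-global aligner."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 \
                or self.gap_extend > 0:
            raise ValueError("match must be > 0; penalties must be <= 0")


DEFAULT_SCORING = AlignScoring()


@numba.njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Fill + traceback. Values are score*_SCALE - internal_gap_columns so the
    fewer-gaps tie-break rides inside one integer comparison.

    Returns (ops, n_ops, i0, j0, ie, je, ident, denom, gapcols, combined).
    ops are backward-ordered: 0 = diagonal, 1 = up (residue of a over a gap),
    2 = left (gap over a residue of b).
    """
    n = a.shape[0]
    m = b.shape[0]
    match_v = np.int32(match * _SCALE)
    mis_v = np.int32(mismatch * _SCALE)
    open_v = np.int32((gap_open + gap_extend) * _SCALE - 1)
    ext_v = np.int32(gap_extend * _SCALE - 1)

    H = np.empty((n + 1, m + 1), np.int32)
    E = np.empty((n + 1, m + 1), np.int32)
    F = np.empty((n + 1, m + 1), np.int32)
    for j in range(m + 1):
        H[0, j] = 0
        E[0, j] = _NEG
        F[0, j] = _NEG
    for i in range(1, n + 1):
        H[i, 0] = 0
        E[i, 0] = _NEG
        F[i, 0] = _NEG
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + ext_v
            t = H[i, j - 1] + open_v
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] + ext_v
            t = H[i - 1, j] + open_v
            if t > f:
                f = t
            F[i, j] = f
            sub = match_v if ai == b[j - 1] else mis_v
            h = H[i - 1, j - 1] + sub
            if f > h:
                h = f
            if e > h:
                h = e
            H[i, j] = h

    # endpoint: free trailing gaps -> max over last row and last column;
    # ties prefer the endpoint with fewest terminal gap columns (max i+j),
    # then larger i.
    best = _NEG
    ie = n
    je = m
    for j in range(m + 1):
        v = H[n, j]
        if v > best or (v == best and (n + j > ie + je)):
            best = v
            ie = n
            je = j
    for i in range(n):
        v = H[i, m]
        if v > best or (v == best and (i + m > ie + je or
                                       (i + m == ie + je and i > ie))):
            best = v
            ie = i
            je = m

    ops = np.empty(n + m, np.int8)
    k = 0
    i = ie
    j = je
    ident = 0
    denom = 0
    gapcols = 0
    state = 0  # 0 = H, 1 = F (up), 2 = E (left)
    while True:
        if state == 0:
            if i == 0 or j == 0:
                break
            sub = match_v if a[i - 1] == b[j - 1] else mis_v
            if H[i, j] == H[i - 1, j - 1] + sub:
                ops[k] = 0
                k += 1
                denom += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            denom += 1
            gapcols += 1
            if F[i, j] == H[i - 1, j] + open_v:
                state = 0
            i -= 1
        else:
            ops[k] = 2
            k += 1
            denom += 1
            gapcols += 1
            if E[i, j] == H[i, j - 1] + open_v:
                state = 0
            j -= 1
    return ops, k, i, j, ie, je, ident, denom, gapcols, best


@dataclass(frozen=True)
class Alignment:
    """A gapped pair covering both sequences, terminal gaps explicit."""

    aligned_a: str
    aligned_b: str
    score: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def gap_columns(self) -> int:
        """Gap columns inside the non-terminal region."""
        lo, hi = _region(self.aligned_a, self.aligned_b)
        return sum(
            1
            for k in range(lo, hi)
            if self.aligned_a[k] == "-" or self.aligned_b[k] == "-"
        )


@dataclass(frozen=True)
class PairStats:
    """Exact integer alignment statistics for one sequence pair."""

    identical: int
    denominator: int
    a_region_residues: int
    b_region_residues: int
    score: int

    def identity(self) -> float:
        if self.denominator == 0:
            return 0.0
        return 100.0 * self.identical / self.denominator

    def coverage_a(self, a_length: int) -> float:
        return 100.0 * self.a_region_residues / a_length if a_length else 0.0

    def coverage_b(self, b_length: int) -> float:
        return 100.0 * self.b_region_residues / b_length if b_length else 0.0


def _core(a: str, b: str, scoring: AlignScoring):
    if not a or not b:
        raise ValueError("align_pair requires nonempty sequences")
    if len(a) > _MAX_LEN or len(b) > _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} nt not supported")
    return _gotoh(
        encode(a),
        encode(b),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )


def align_pair(a: str, b: str, scoring: AlignScoring = DEFAULT_SCORING) -> Alignment:
    """Optimal semi-global alignment of ``a`` (rows) against ``b``."""
    ops, k, i0, j0, ie, je, _ident, _denom, gapcols, best = _core(a, b, scoring)
    rows_a: list[str] = []
    rows_b: list[str] = []
    if i0 > 0:
        rows_a.append(a[:i0])
        rows_b.append("-" * i0)
    if j0 > 0:
        rows_a.append("-" * j0)
        rows_b.append(b[:j0])
    pa, pb = i0, j0
    for t in range(k - 1, -1, -1):
        op = ops[t]
        if op == 0:
            rows_a.append(a[pa])
            rows_b.append(b[pb])
            pa += 1
            pb += 1
        elif op == 1:
            rows_a.append(a[pa])
            rows_b.append("-")
            pa += 1
        else:
            rows_a.append("-")
            rows_b.append(b[pb])
            pb += 1
    if ie < len(a):
        rows_a.append(a[ie:])
        rows_b.append("-" * (len(a) - ie))
    if je < len(b):
        rows_a.append("-" * (len(b) - je))
        rows_b.append(b[je:])
    score = int((best + gapcols) // _SCALE)
    return Alignment("".join(rows_a), "".join(rows_b), score)


def _region(row_a: str, row_b: str) -> tuple[int, int]:
    """Column range [lo, hi) excluding terminal-gap columns of either row."""
    def span(row: str) -> tuple[int, int]:
        first = len(row) - len(row.lstrip("-"))
        last = len(row.rstrip("-"))
        return first, last

    a_lo, a_hi = span(row_a)
    b_lo, b_hi = span(row_b)
    lo, hi = max(a_lo, b_lo), min(a_hi, b_hi)
    return (lo, hi) if lo < hi else (0, 0)


def identity_and_coverage(
    alignment: Alignment, query_length: int, query_row: str = "a"
) -> tuple[float, float]:
    """Percent identity and query coverage of an alignment.

    ``query_row`` names which alignment row is the query ("a" or "b"); only
    coverage depends on it. A degenerate alignment with no aligned region
    reports (0.0, 0.0).
    """
    ra, rb = alignment.aligned_a, alignment.aligned_b
    lo, hi = _region(ra, rb)
    if hi == lo:
        return 0.0, 0.0
    ident = sum(1 for k in range(lo, hi) if ra[k] == rb[k] and ra[k] != "-")
    qrow = ra if query_row == "a" else rb
    qres = sum(1 for k in range(lo, hi) if qrow[k] != "-")
    return 100.0 * ident / (hi - lo), 100.0 * qres / query_length


def pair_stats(a: str, b: str, scoring: AlignScoring = DEFAULT_SCORING) -> PairStats:
    """Alignment statistics for an unordered pair.

    The pair is aligned in a canonical orientation (shorter, then
    lexicographically smaller, sequence first) so that identity is exactly
    symmetric even when co-optimal alignments disagree; both orientations'
    coverages come from the same alignment.
    """
    swapped = (len(b), b) < (len(a), a)
    x, y = (b, a) if swapped else (a, b)
    _ops, _k, i0, j0, ie, je, ident, denom, gapcols, best = _core(x, y, scoring)
    xres, yres = ie - i0, je - j0
    if swapped:
        xres, yres = yres, xres
    return PairStats(
        identical=ident,
        denominator=denom,
        a_region_residues=xres,
        b_region_residues=yres,
        score=int((best + gapcols) // _SCALE),
    )


@dataclass(frozen=True)
class IdentityHit:
    """One pairwise identity/coverage result.

    ``identical``/``denominator`` are exact integer column counts; the decision
    rules compare them as rationals. ``coverage`` is relative to ``query_id``'s
    sequence; identity is symmetric in query and subject.
    """

    query_id: str
    subject_id: str
    marker_scope: str
    identical: int
    denominator: int
    aligned_columns: int
    query_region_residues: int
    query_length: int

    @property
    def identity(self) -> float:
        if self.denominator == 0:
            return 0.0
        return 100.0 * self.identical / self.denominator

    @property
    def coverage(self) -> float:
        if self.query_length == 0:
            return 0.0
        return 100.0 * self.query_region_residues / self.query_length

    @property
    def identity_fraction(self) -> Fraction:
        if self.denominator == 0:
            return Fraction(0)
        return Fraction(self.identical, self.denominator)


def _hit_from_stats(
    qid: str, sid: str, scope: str, st: PairStats, qlen: int
) -> IdentityHit:
    return IdentityHit(
        query_id=qid,
        subject_id=sid,
        marker_scope=scope,
        identical=st.identical,
        denominator=st.denominator,
        aligned_columns=st.denominator,
        query_region_residues=st.a_region_residues,
        query_length=qlen,
    )


def all_pairs_identity(
    lib,
    marker: str,
    scoring: AlignScoring = DEFAULT_SCORING,
    min_hit_columns: int = MIN_HIT_COLUMNS,
) -> list[IdentityHit]:
    """All-to-all identity over the library's records of one marker.

    One hit per unordered specimen pair; self-hits excluded; pairs whose
    aligned region is shorter than ``min_hit_columns`` produce no hit (see
    MIN_HIT_COLUMNS). With fewer than two records an empty list is returned
    with a logged warning.
    """
    recs = sorted(lib.records_for_marker(marker), key=lambda r: r.specimen_id)
    if len(recs) < 2:
        logger.warning("marker %s has %d record(s); no pairs", marker, len(recs))
        return []
    hits = []
    for ra, rb in itertools.combinations(recs, 2):
        st = pair_stats(ra.sequence, rb.sequence, scoring)
        if st.denominator < min_hit_columns:
            continue
        hits.append(
            _hit_from_stats(
                ra.specimen_id, rb.specimen_id, marker, st, len(ra.sequence)
            )
        )
    return hits


def combined_identity(
    lib,
    specimen_a: str,
    specimen_b: str,
    markers: Sequence[str],
    scoring: AlignScoring = DEFAULT_SCORING,
    min_hit_columns: int = MIN_HIT_COLUMNS,
) -> IdentityHit | None:
    """Pooled identity over the markers both specimens share.

    Per shared marker, identical and denominator columns are counted as usual
    and pooled: identity = 100 x sum(identical) / sum(denominator). A marker
    whose aligned region falls below ``min_hit_columns`` contributes nothing.
    Returns None (with a log record) if the pair shares no marker.
    """
    ident = denom = qres = qlen = 0
    shared = False
    for marker in markers:
        sa = lib.sequence(specimen_a, marker)
        sb = lib.sequence(specimen_b, marker)
        if sa is None or sb is None:
            continue
        st = pair_stats(sa, sb, scoring)
        if st.denominator < min_hit_columns:
            continue
        shared = True
        ident += st.identical
        denom += st.denominator
        qres += st.a_region_residues
        qlen += len(sa)
    if not shared:
        logger.info(
            "specimens %s and %s share no marker from %s",
            specimen_a, specimen_b, list(markers),
        )
        return None
    return IdentityHit(
        query_id=specimen_a,
        subject_id=specimen_b,
        marker_scope="combined",
        identical=ident,
        denominator=denom,
        aligned_columns=denom,
        query_region_residues=qres,
        query_length=qlen,
    )


def all_pairs_combined(
    lib,
    markers: Sequence[str],
    scoring: AlignScoring = DEFAULT_SCORING,
    per_marker_hits: Mapping[str, Iterable[IdentityHit]] | None = None,
    min_hit_columns: int = MIN_HIT_COLUMNS,
) -> list[IdentityHit]:
    """Pooled all-to-all hits over a marker combination.

    Reuses precomputed per-marker hit tables when given (the pooled counts
    are plain sums); per-marker contributions below ``min_hit_columns``
    aligned columns are dropped, and pairs sharing no (alignable) marker are
    excluded.
    """
    seqs: dict[str, dict[str, str]] = {}
    for marker in markers:
        for rec in lib.records_for_marker(marker):
            seqs.setdefault(rec.specimen_id, {})[marker] = rec.sequence
    specimens = sorted(seqs)

    cache: dict[tuple[str, str, str], IdentityHit] = {}
    cached_markers: set[str] = set()
    if per_marker_hits:
        for marker, hits in per_marker_hits.items():
            cached_markers.add(marker)
            for h in hits:
                cache[(h.query_id, h.subject_id, marker)] = h

    out: list[IdentityHit] = []
    for qa, qb in itertools.combinations(specimens, 2):
        ident = denom = qres = qlen = 0
        shared = False
        for marker in markers:
            sa = seqs[qa].get(marker)
            sb = seqs[qb].get(marker)
            if sa is None or sb is None:
                continue
            if marker in cached_markers:
                # absence from a provided table means the pair fell below the
                # evidence floor for this marker
                h = cache.get((qa, qb, marker))
                if h is None or h.denominator < min_hit_columns:
                    continue
                shared = True
                ident += h.identical
                denom += h.denominator
                qres += h.query_region_residues
                qlen += h.query_length
            else:
                st = pair_stats(sa, sb, scoring)
                if st.denominator < min_hit_columns:
                    continue
                shared = True
                ident += st.identical
                denom += st.denominator
                qres += st.a_region_residues
                qlen += len(sa)
        if not shared:
            continue
        out.append(
            IdentityHit(
                query_id=qa,
                subject_id=qb,
                marker_scope="combined",
                identical=ident,
                denominator=denom,
                aligned_columns=denom,
                query_region_residues=qres,
                query_length=qlen,
            )
        )
    return out


def hits_to_frame(hits: Iterable[IdentityHit]) -> pd.DataFrame:
    """Hit table as a DataFrame (TSV column order of the writers)."""
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "marker_scope": h.marker_scope,
                "identity": h.identity,
                "coverage": h.coverage,
                "aligned_columns": h.aligned_columns,
                "identical": h.identical,
                "denominator": h.denominator,
            }
            for h in hits
        ],
        columns=[
            "query_id", "subject_id", "marker_scope", "identity", "coverage",
            "aligned_columns", "identical", "denominator",
        ],
    )


def write_hits(hits: Iterable[IdentityHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
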
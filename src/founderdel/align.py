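"""Exact read alignment for a small locus: affine-gap local DP plus an
optional single long reference gap (split alignment across a deletion).

The locus is a few kilobases, so instead of seed-and-extend heuristics the
aligner computes the exact optimum: a Smith-Waterman local alignment with
affine gaps, and -- when ``allow_long_deletion`` is on -- the best
prefix+suffix split joined over every candidate junction with one reference
gap of at least ``min_del_len`` bp, charged a flat penalty.  The higher of
the two is returned; among equal-score alignments the leftmost reference
placement wins (a split whose prefix anchors upstream beats a contiguous
placement further right), then the plus strand, then the contiguous form.

Recurrences (shared with the brute-force oracle used in the tests):
``M`` opens from any state diagonally with a zero floor (local), ``Ix``
(reference gap) opens from ``M`` within the row, ``Iy`` (read gap) opens
from ``M`` within the column; gaps never chain into each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locus import BASES, LocusReference, revcomp

_NEG = np.int32(-(10**8))


class AlignmentInputError(ValueError):
    """Raised for malformed alignment inputs (e.g. non-ACGT characters)."""


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4  # first gapped base
    gap_extend: int = -1  # each further gapped base
    long_del_penalty: int = -6  # flat charge for the long reference gap
    min_del_len: int = 50

    def validate(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise AlignmentInputError("scoring requires match>0 and mismatch<0")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise AlignmentInputError("gap penalties must be negative")


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    """A (possibly split) local alignment of one read against the reference.

    ``segments`` are gap-free aligned blocks ``((read_lo, read_hi),
    (ref_lo, ref_hi))``, ordered and non-overlapping in both coordinate
    systems.  Read coordinates refer to the aligned orientation (the
    reverse complement for ``strand == '-'``).  ``long_deletion`` is the
    reference interval skipped by the split, if any.
    """

    read_id: str
    strand: str
    segments: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    mismatch_positions: tuple[int, ...]  # reference coordinates
    long_deletion: tuple[int, int] | None
    score: int
    read_codes: np.ndarray | None = field(default=None, compare=False, repr=False)

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.segments[0][1][0], self.segments[-1][1][1]

    @property
    def is_split(self) -> bool:
        return self.long_deletion is not None


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    codes = lut[arr]
    if (codes < 0).any():
        bad = seq[int(np.argmax(lut[arr] < 0))]
        raise AlignmentInputError(f"non-ACGT character {bad!r} in sequence")
    return codes.astype(np.int8)


def _sw_matrices(read: np.ndarray, ref: np.ndarray, sc: Scoring):
    """Forward local-alignment matrices, vectorized along the reference axis.

    ``M[i, j]`` is the best local alignment score ending with ``read[i-1]``
    aligned to ``ref[j-1]``.  The within-row ``Ix`` recurrence is closed-form:
    ``Ix[i, j] = max_k (M[i, k] - k*ext) + open + (j-1)*ext`` via a running
    maximum, which is exactly the open-from-M affine chain.
    """
    n, m = len(read), len(ref)
    M = np.full((n + 1, m + 1), 0, dtype=np.int32)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    j_idx = np.arange(m + 1, dtype=np.int32)
    ext = np.int32(sc.gap_extend)
    for i in range(1, n + 1):
        sub = np.where(ref == read[i - 1], sc.match, sc.mismatch).astype(np.int32)
        prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = np.maximum(0, prev[:-1] + sub)
        Iy[i, 1:] = np.maximum(M[i - 1, 1:] + sc.gap_open, Iy[i - 1, 1:] + ext)
        run = np.maximum.accumulate(M[i, :m] - j_idx[:m] * ext)
        Ix[i, 1:] = run + sc.gap_open + (j_idx[1:] - 1) * ext
    return M, Ix, Iy


def _traceback(M, Ix, Iy, read, ref, sc: Scoring, i: int, j: int):
    """Walk back from ``M[i, j]`` to the local start; return aligned pairs."""
    pairs: list[tuple[int, int]] = []  # (read_idx, ref_idx) aligned positions
    state = "M"
    while True:
        if state == "M":
            sub = sc.match if ref[j - 1] == read[i - 1] else sc.mismatch
            pairs.append((i - 1, j - 1))
            prev = int(M[i, j]) - sub
            i, j = i - 1, j - 1
            if prev == 0:
                break
            if M[i, j] == prev:
                state = "M"
            elif Iy[i, j] == prev:
                state = "Iy"
            elif Ix[i, j] == prev:
                state = "Ix"
            else:  # pragma: no cover - recurrence violation
                raise AssertionError("traceback failed in M")
        elif state == "Ix":
            if Ix[i, j] == M[i, j - 1] + sc.gap_open:
                state = "M"
            j -= 1
        else:  # Iy
            if Iy[i, j] == M[i - 1, j] + sc.gap_open:
                state = "M"
            i -= 1
    pairs.reverse()
    return pairs


def _pairs_to_segments(pairs, read, ref):
    """Group aligned pairs into gap-free blocks; collect mismatch ref coords."""
    segments = []
    mismatches = []
    start = 0
    for k in range(1, len(pairs) + 1):
        if (
            k == len(pairs)
            or pairs[k][0] != pairs[k - 1][0] + 1
            or pairs[k][1] != pairs[k - 1][1] + 1
        ):
            r0, g0 = pairs[start]
            r1, g1 = pairs[k - 1]
            segments.append(((r0, r1 + 1), (g0, g1 + 1)))
            start = k
    for ri, gi in pairs:
        if read[ri] != ref[gi]:
            mismatches.append(gi)
    return tuple(segments), tuple(mismatches)


def _best_cell(M) -> tuple[int, int, int]:
    flat = int(np.argmax(M))
    i, j = divmod(flat, M.shape[1])
    return int(M[i, j]), i, j


def _best_split(Mf, Mr, n: int, m: int, sc: Scoring):
    """Best prefix+suffix join with one reference gap >= ``min_del_len``.

    Returns ``(score, i, p, q)``: the read splits after ``i`` bases, the
    prefix ends at reference position ``p`` and the suffix resumes at ``q``
    (the deleted interval is ``[p, q)``).  Ties resolve to the smallest
    ``i`` then the leftmost ``q`` and ``p`` -- with homology at the junction
    this is the leftmost equivalent placement.
    """
    mdl = sc.min_del_len
    if m <= mdl:
        return None
    best = (_NEG, -1, -1, -1)
    q_idx = np.arange(mdl, m + 1)
    for i in range(1, n):
        A = np.where(Mf[i] > 0, Mf[i], _NEG)
        B_row = Mr[n - i][::-1]  # B[q] = Mr[n-i][m-q]
        B = np.where(B_row > 0, B_row, _NEG)
        pre = np.maximum.accumulate(A)
        vals = pre[q_idx - mdl] + B[q_idx]
        k = int(np.argmax(vals))
        sc_i = int(vals[k])
        if sc_i > best[0]:
            q = int(q_idx[k])
            p = int(np.argmax(A[: q - mdl + 1]))
            best = (sc_i, i, p, q)
    if best[1] < 0 or best[0] <= 0:  # no positive prefix+suffix combination
        return None
    return best[0] + sc.long_del_penalty, best[1], best[2], best[3]


def _align_one_strand(read_codes, ref_codes, sc: Scoring, allow_long_deletion: bool):
    """Return a list of (score, kind, payload) candidates for one strand."""
    n, m = len(read_codes), len(ref_codes)
    Mf, Ixf, Iyf = _sw_matrices(read_codes, ref_codes, sc)
    best_score, bi, bj = _best_cell(Mf)
    out = [(best_score, "contig", (Mf, Ixf, Iyf, bi, bj))]
    if allow_long_deletion:
        rev_read = read_codes[::-1].copy()
        rev_ref = ref_codes[::-1].copy()
        Mr, Ixr, Iyr = _sw_matrices(rev_read, rev_ref, sc)
        split = _best_split(Mf, Mr, n, m, sc)
        if split is not None and split[0] >= best_score:
            score, i, p, q = split
            out.append((score, "split", (Mf, Ixf, Iyf, Mr, Ixr, Iyr, i, p, q)))
    return out


def align_read(
    read: str,
    ref: "LocusReference | str",
    scoring: Scoring = DEFAULT_SCORING,
    allow_long_deletion: bool = False,
    read_id: str = "read",
) -> AlignmentResult:
    """Exact best local alignment of ``read`` against ``ref`` (both strands).

    With ``allow_long_deletion`` the optimum is taken over contiguous local
    alignments *and* prefix+suffix splits carrying one reference gap of at
    least ``scoring.min_del_len`` bp (flat penalty).  Raises
    :class:`AlignmentInputError` on empty or non-ACGT reads.
    """
    scoring.validate()
    if not read:
        raise AlignmentInputError("empty read")
    ref_seq = ref.sequence if isinstance(ref, LocusReference) else ref
    read_codes = encode(read)
    ref_codes = encode(ref_seq)

    # exact-substring shortcut: a full-length gap-free exact match is always
    # optimal (every alternative scores <= len * match), and str.find gives
    # the leftmost placement required by the tie-break convention.
    n = len(read)
    for strand, seq in (("+", read), ("-", revcomp(read))):
        pos = ref_seq.find(seq)
        if pos >= 0:
            return AlignmentResult(
                read_id=read_id,
                strand=strand,
                segments=(((0, n), (pos, pos + n)),),
                mismatch_positions=(),
                long_deletion=None,
                score=n * scoring.match,
                read_codes=encode(seq),
            )

    candidates = []
    for strand, codes in (("+", read_codes), ("-", encode(revcomp(read)))):
        for score, kind, payload in _align_one_strand(
            codes, ref_codes, scoring, allow_long_deletion
        ):
            candidates.append((score, strand, kind, codes, payload))
    top = max(c[0] for c in candidates)
    finalists = [
        _materialize(score, strand, kind, codes, payload, ref_codes, scoring, read_id)
        for score, strand, kind, codes, payload in candidates
        if score == top
    ]
    # tie-break: leftmost reference placement, then plus strand, then the
    # contiguous (non-split) form
    finalists.sort(key=lambda a: (a.ref_span[0], a.strand != "+", a.is_split))
    return finalists[0]


def _materialize(score, strand, kind, codes, payload, ref_codes, scoring, read_id):
    if kind == "contig":
        Mf, Ixf, Iyf, bi, bj = payload
        pairs = _traceback(Mf, Ixf, Iyf, codes, ref_codes, scoring, bi, bj)
        segments, mismatches = _pairs_to_segments(pairs, codes, ref_codes)
        long_del = None
    else:
        Mf, Ixf, Iyf, Mr, Ixr, Iyr, i, p, q = payload
        m = len(ref_codes)
        pre_pairs = _traceback(Mf, Ixf, Iyf, codes, ref_codes, scoring, i, p)
        rev_codes = codes[::-1].copy()
        rev_ref = ref_codes[::-1].copy()
        suf_rev = _traceback(
            Mr, Ixr, Iyr, rev_codes, rev_ref, scoring, len(codes) - i, m - q
        )
        suf_pairs = [(len(codes) - 1 - ri, m - 1 - gi) for ri, gi in suf_rev]
        suf_pairs.reverse()
        pairs = pre_pairs + suf_pairs
        segments, mismatches = _pairs_to_segments(pairs, codes, ref_codes)
        long_del = (p, q)
    return AlignmentResult(
        read_id=read_id,
        strand=strand,
        segments=segments,
        mismatch_positions=mismatches,
        long_deletion=long_del,
        score=int(score),
        read_codes=codes,
    )
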
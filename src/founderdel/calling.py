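"""Deletion genotyping, breakpoint microhomology resolution, and artefact-SNV
detection from read alignments.

The artefact mechanism: reads spanning the deletion junction, force-aligned
without a long gap, are mapped onto one repeat copy only; wherever the two
copies differ, the bases of the other copy surface as apparent heterozygous
SNVs.  Allowing the long gap realigns those reads across the junction and the
spurious calls vanish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import AlignmentResult, DEFAULT_SCORING, Scoring, align_read, encode
from .locus import LocusReference, ReadSet, homology_run


class SpanningConflictError(ValueError):
    """Spanning reads imply different deleted sequences."""

    def __init__(self, read_ids):
        self.read_ids = tuple(read_ids)
        super().__init__(
            "inconsistent spanning alignments (different implied alt sequences): "
            + ", ".join(self.read_ids)
        )


@dataclass(frozen=True)
class GenotypeThresholds:
    """Banding of the spanning-read fraction among junction-informative reads."""

    hom_alt_min_frac: float = 0.85
    hom_ref_max_frac: float = 0.15
    min_informative: int = 8
    anchor_margin: int = 10  # bases a ref-junction read must extend past homology


@dataclass(frozen=True)
class DeletionGenotype:
    spanning_read_count: int
    ref_junction_read_count: int
    genotype: str  # "ref/ref" | "ref/del" | "del/del" | "no-call"
    spanning_read_ids: tuple[str, ...]
    ref_junction_read_ids: tuple[str, ...]


@dataclass(frozen=True)
class MicrohomologyInterval:
    """Admissible left-breakpoint coordinates and the homology length."""

    placement_interval: tuple[int, int]  # half-open, reference coordinates
    homology_length: int

    def __post_init__(self):
        lo, hi = self.placement_interval
        assert self.homology_length == (hi - lo) - 1 >= 0


@dataclass(frozen=True)
class VariantCall:
    position: int  # 0-based reference coordinate
    ref_base: str
    alt_base: str
    depth: int
    fraction: float


@dataclass(frozen=True)
class ArtefactSite:
    position: int
    alt_fraction: float
    depth: int
    inside_divergent_set: bool


@dataclass(frozen=True)
class ArtefactReport:
    sites: tuple[ArtefactSite, ...]

    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def _as_read_iter(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, ReadSet):
        return reads.sequences()
    return reads


def align_all(
    reads,
    ref: LocusReference,
    scoring: Scoring = DEFAULT_SCORING,
    allow_long_deletion: bool = True,
) -> list[AlignmentResult]:
    """Align every read (``ReadSet`` or ``(id, seq)`` iterable) against ``ref``."""
    return [
        align_read(seq, ref, scoring, allow_long_deletion, read_id=rid)
        for rid, seq in _as_read_iter(reads)
    ]


def canonical_deletion(ref_seq: str, long_deletion: tuple[int, int]) -> tuple[int, int]:
    """Normalize a split placement to its leftmost equivalent coordinates."""
    p, q = long_deletion
    lo, _ = homology_run(ref_seq, p, q - p)
    return lo, lo + (q - p)


def resolve_microhomology(
    ref: LocusReference, alignments: Sequence[AlignmentResult]
) -> MicrohomologyInterval:
    """Breakpoint ambiguity from spanning alignments.

    All spanning reads must imply the same deleted sequence once placements
    are normalized; otherwise a :class:`SpanningConflictError` lists the
    offending reads.  The homology length ``h`` equals the number of
    admissible left-breakpoint placements minus one.
    """
    spanning = [a for a in alignments if a.long_deletion is not None]
    if not spanning:
        raise ValueError("no spanning alignments provided")
    canon = {a.read_id: canonical_deletion(ref.sequence, a.long_deletion) for a in spanning}
    unique = set(canon.values())
    if len(unique) > 1:
        raise SpanningConflictError(sorted(canon))
    (p0, q0), = unique
    lo, placements = homology_run(ref.sequence, p0, q0 - p0)
    return MicrohomologyInterval(
        placement_interval=(lo, lo + placements), homology_length=placements - 1
    )


def genotype_deletion(
    reads,
    ref: LocusReference,
    scoring: Scoring = DEFAULT_SCORING,
    thresholds: GenotypeThresholds | None = None,
    alignments: Sequence[AlignmentResult] | None = None,
) -> DeletionGenotype:
    """Genotype the locus deletion from spanning vs reference-junction reads.

    A read supports the deletion if its long-gap placement normalizes to the
    locus ``deletion_span``.  A read supports the reference junction if it
    aligns contiguously across a breakpoint window extended by the homology
    length plus a margin, with no mismatches inside the window -- reads that
    merely end inside the homologous core are ambiguous and count for
    neither allele.
    """
    th = thresholds or GenotypeThresholds()
    if alignments is None:
        alignments = align_all(reads, ref, scoring, allow_long_deletion=True)

    del_start, del_end = ref.deletion_span
    lo, placements = homology_run(ref.sequence, del_start, del_end - del_start)
    h = placements - 1
    m = th.anchor_margin
    windows = (
        (del_start - m, del_start + h + m),  # left breakpoint + homology
        (del_end - m, del_end + h + m),  # right breakpoint + homology image
    )

    spanning_ids, ref_ids = [], []
    for a in alignments:
        if a.long_deletion is not None:
            if canonical_deletion(ref.sequence, a.long_deletion) == (del_start, del_end):
                spanning_ids.append(a.read_id)
            continue
        span = a.ref_span
        for wlo, whi in windows:
            covered = span[0] <= wlo and span[1] >= whi
            if covered and not any(wlo <= pos < whi for pos in a.mismatch_positions):
                ref_ids.append(a.read_id)
                break

    n_span, n_ref = len(spanning_ids), len(ref_ids)
    informative = n_span + n_ref
    if informative < th.min_informative:
        genotype = "no-call"
    else:
        frac = n_span / informative
        if frac >= th.hom_alt_min_frac:
            genotype = "del/del"
        elif frac <= th.hom_ref_max_frac:
            genotype = "ref/ref"
        else:
            genotype = "ref/del"
    return DeletionGenotype(
        spanning_read_count=n_span,
        ref_junction_read_count=n_ref,
        genotype=genotype,
        spanning_read_ids=tuple(spanning_ids),
        ref_junction_read_ids=tuple(ref_ids),
    )


def pileup_variants(
    alignments: Sequence[AlignmentResult],
    ref: LocusReference,
    min_depth: int = 8,
    min_fraction: float = 0.25,
) -> list[VariantCall]:
    """Simple substitution pileup over gap-free aligned blocks.

    One call per reference position where depth >= ``min_depth`` and the most
    frequent non-reference base reaches ``min_fraction`` of the depth.
    """
    ref_codes = encode(ref.sequence)
    m = len(ref_codes)
    counts = np.zeros((4, m), dtype=np.int64)
    for a in alignments:
        if a.read_codes is None:
            raise ValueError(f"alignment {a.read_id} lacks read bases")
        for (r0, r1), (g0, g1) in a.segments:
            np.add.at(counts, (a.read_codes[r0:r1], np.arange(g0, g1)), 1)
    depth = counts.sum(axis=0)
    calls: list[VariantCall] = []
    bases = "ACGT"
    for pos in np.nonzero(depth >= min_depth)[0]:
        col = counts[:, pos].copy()
        r = ref_codes[pos]
        col[r] = 0
        alt = int(np.argmax(col))
        frac = col[alt] / depth[pos]
        if col[alt] > 0 and frac >= min_fraction:
            calls.append(
                VariantCall(
                    position=int(pos),
                    ref_base=bases[r],
                    alt_base=bases[alt],
                    depth=int(depth[pos]),
                    fraction=float(frac),
                )
            )
    return calls


def flag_artefact_snvs(
    calls_unaware: Sequence[VariantCall],
    calls_aware: Sequence[VariantCall],
    ref: LocusReference,
) -> ArtefactReport:
    """Variants present only under deletion-unaware alignment, annotated
    against the planted divergent repeat offsets."""
    aware_positions = {c.position for c in calls_aware}
    divergent = ref.divergent_ref_positions()
    sites = tuple(
        ArtefactSite(
            position=c.position,
            alt_fraction=c.fraction,
            depth=c.depth,
            inside_divergent_set=c.position in divergent,
        )
        for c in calls_unaware
        if c.position not in aware_positions
    )
    return ArtefactReport(sites=sites)


def warn_low_depth(calls: Sequence[VariantCall], min_depth: int = 8) -> None:
    low = [c for c in calls if c.depth < min_depth]
    if low:
        warnings.warn(f"{len(low)} calls below depth {min_depth}", stacklevel=2)
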
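"""Synthetic locus fixtures: reference with imperfect flanking repeats,
a founder deletion with planted breakpoint microhomology, and reads.

The locus emulates a gene disrupted by a ~5.2-kb founder deletion whose
breakpoints fall inside an identical core shared by two near-identical
120-bp repeat copies.  The two copies differ at a configurable number of
divergent positions; the stretch over which they are identical around the
breakpoints (the *core*) is what makes the junction coordinate ambiguous
(breakpoint microhomology) and what produces artefact SNVs under
deletion-unaware alignment.

Coordinates are 0-based half-open throughout; 1-based conventions appear
only at VCF/TSV boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class LocusConfigError(ValueError):
    """Raised when a locus/read configuration violates a structural constraint."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusConfig:
    """Geometry of the synthetic locus.

    ``repeat_len`` bp repeat copies differ at ``n_divergent`` offsets and are
    identical over a ``core_len`` bp core that contains both deletion
    breakpoints.  The deletion removes exactly ``deletion_len`` bp, fusing the
    two repeat copies into one chimeric copy, and excises all exons except the
    last one.
    """

    repeat_len: int = 120
    n_divergent: int = 15
    core_len: int = 23
    deletion_len: int = 5200
    left_flank: int = 1200
    right_flank: int = 1200
    core_offset: int | None = None  # within-repeat start of the identical core
    n_exons: int = 5
    exon_len: int = 150

    def resolved_core_offset(self) -> int:
        if self.core_offset is not None:
            return self.core_offset
        return max(1, (self.repeat_len - self.core_len) // 2)

    def validate(self, read_len: int = 150) -> None:
        co = self.resolved_core_offset()
        if self.repeat_len < self.core_len + self.n_divergent:
            raise LocusConfigError(
                "repeat_len must be >= core_len + n_divergent "
                f"({self.repeat_len} < {self.core_len} + {self.n_divergent})"
            )
        if self.deletion_len <= 2 * read_len:
            raise LocusConfigError(
                f"deletion_len must exceed twice the read length "
                f"({self.deletion_len} <= {2 * read_len})"
            )
        if not (1 <= co and co + self.core_len <= self.repeat_len - 1):
            raise LocusConfigError(
                "core span must leave at least one within-repeat position on "
                f"each side (core_offset={co}, core_len={self.core_len}, "
                f"repeat_len={self.repeat_len})"
            )
        gap = self.deletion_len - self.repeat_len
        if gap < (self.n_exons - 1) * (self.exon_len + 50) + 100:
            raise LocusConfigError(
                "deletion_len too small to host the excised exons between the "
                "repeat copies"
            )
        if self.n_divergent < 0 or self.core_len < 0:
            raise LocusConfigError("n_divergent and core_len must be non-negative")


@dataclass(frozen=True)
class LocusReference:
    """A synthetic reference segment with annotated repeat/deletion structure.

    Attributes
    ----------
    sequence
        Reference nucleotide string.
    repeat_a_span, repeat_b_span
        0-based half-open intervals of the two repeat copies.
    divergent_positions
        Sorted within-repeat offsets at which the copies differ.
    core_span
        Within-repeat half-open interval over which the copies are identical
        and inside which both deletion breakpoints fall.
    exon_spans
        Half-open intervals of the exons; all but the last lie inside the
        deletion.
    deletion_span
        Canonical (leftmost) placement of the deletion, half-open.
    """

    sequence: str
    repeat_a_span: tuple[int, int]
    repeat_b_span: tuple[int, int]
    repeat_len: int
    divergent_positions: tuple[int, ...]
    core_span: tuple[int, int]
    exon_spans: tuple[tuple[int, int], ...]
    deletion_span: tuple[int, int]
    config: LocusConfig = field(default_factory=LocusConfig)

    @property
    def deletion_len(self) -> int:
        s, e = self.deletion_span
        return e - s

    def divergent_ref_positions(self) -> frozenset[int]:
        """Absolute reference coordinates of divergent offsets in both copies."""
        a0 = self.repeat_a_span[0]
        b0 = self.repeat_b_span[0]
        return frozenset(a0 + d for d in self.divergent_positions) | frozenset(
            b0 + d for d in self.divergent_positions
        )

    def validate(self) -> None:
        seq = self.sequence
        a0, a1 = self.repeat_a_span
        b0, b1 = self.repeat_b_span
        assert a1 - a0 == b1 - b0 == self.repeat_len
        div = set(self.divergent_positions)
        for off in range(self.repeat_len):
            same = seq[a0 + off] == seq[b0 + off]
            if off in div:
                assert not same, f"copies identical at divergent offset {off}"
            else:
                assert same, f"copies differ at non-divergent offset {off}"
        c0, c1 = self.core_span
        assert not (div & set(range(c0, c1))), "divergent offset inside core"
        ds, de = self.deletion_span
        assert a0 + c0 <= ds <= a0 + c1, "left breakpoint outside core-aligned span"
        assert b0 + c0 <= de <= b0 + c1, "right breakpoint outside core-aligned span"
        assert de - ds == self.config.deletion_len


@dataclass(frozen=True)
class DeletionAllele:
    """The deletion haplotype: reference with ``deletion_span`` excised."""

    alt_sequence: str
    junction_offset: int  # position of the fused junction in alt coordinates
    equivalent_placements: int  # junction coordinates yielding identical alt


def build_locus(params: LocusConfig | None = None, seed: int = 0) -> LocusReference:
    """Generate a synthetic locus per ``params``, deterministically for ``seed``.

    The two repeat copies are placed exactly ``deletion_len`` bp apart so that
    excising the canonical deletion fuses them into a single chimeric copy.
    When ``n_divergent >= 2``, the offsets immediately flanking the core are
    forced to be divergent, so the microhomology run equals the core length
    exactly.
    """
    cfg = params or LocusConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    co = cfg.resolved_core_offset()

    a0 = cfg.left_flank
    b0 = a0 + cfg.deletion_len
    total = b0 + cfg.repeat_len + cfg.right_flank
    codes = rng.integers(0, 4, size=total)
    # copy repeat A onto the B location, then re-diverge selected offsets
    codes[b0 : b0 + cfg.repeat_len] = codes[a0 : a0 + cfg.repeat_len]

    forced = [off for off in (co - 1, co + cfg.core_len) if 0 <= off < cfg.repeat_len]
    forced = forced[: cfg.n_divergent]
    pool = [
        off
        for off in range(cfg.repeat_len)
        if off not in forced and not (co <= off < co + cfg.core_len)
    ]
    extra = sorted(
        rng.choice(pool, size=cfg.n_divergent - len(forced), replace=False).tolist()
    )
    divergent = tuple(sorted(forced + extra))
    for off in divergent:
        old = codes[b0 + off]
        codes[b0 + off] = (old + 1 + rng.integers(0, 3)) % 4

    # exons: all but the last between the repeat copies, the last downstream
    inner_lo = a0 + cfg.repeat_len + 50
    inner_hi = b0 - 50
    n_inner = cfg.n_exons - 1
    step = (inner_hi - inner_lo) // n_inner
    exons = [
        (inner_lo + i * step, inner_lo + i * step + cfg.exon_len) for i in range(n_inner)
    ]
    last0 = b0 + cfg.repeat_len + 50
    exons.append((last0, min(last0 + cfg.exon_len, total)))

    seq = "".join(BASES[c] for c in codes)
    ref = LocusReference(
        sequence=seq,
        repeat_a_span=(a0, a0 + cfg.repeat_len),
        repeat_b_span=(b0, b0 + cfg.repeat_len),
        repeat_len=cfg.repeat_len,
        divergent_positions=divergent,
        core_span=(co, co + cfg.core_len),
        exon_spans=tuple(exons),
        deletion_span=(a0 + co, a0 + co + cfg.deletion_len),
        config=cfg,
    )
    return ref


def homology_run(sequence: str, del_start: int, del_len: int) -> tuple[int, int]:
    """Equivalent placements of a deletion ``[s, s+del_len)`` around ``del_start``.

    Returns ``(leftmost_start, n_placements)``: all starts ``s`` in
    ``[leftmost_start, leftmost_start + n_placements)`` yield byte-identical
    deleted sequences.  ``n_placements - 1`` is the microhomology length.
    """
    s, e = del_start, del_start + del_len
    kl = 0
    while s - 1 - kl >= 0 and sequence[s - 1 - kl] == sequence[e - 1 - kl]:
        kl += 1
    kr = 0
    while e + kr < len(sequence) and sequence[s + kr] == sequence[e + kr]:
        kr += 1
    return s - kl, kl + kr + 1


def apply_deletion(ref: LocusReference) -> DeletionAllele:
    """Excise the canonical deletion span and report junction ambiguity."""
    s, e = ref.deletion_span
    alt = ref.sequence[:s] + ref.sequence[e:]
    _, placements = homology_run(ref.sequence, s, e - s)
    return DeletionAllele(
        alt_sequence=alt, junction_offset=s, equivalent_placements=placements
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadConfig:
    read_len: int = 150
    coverage: float = 30.0
    error_rate: float = 0.0
    insert_mean: float = 300.0
    insert_sd: float = 30.0

    def validate(self) -> None:
        if self.coverage <= 0 or self.read_len <= 0:
            raise LocusConfigError("coverage and read_len must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise LocusConfigError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str  # forward-strand mate
    seq2: str  # reverse-strand mate (reverse-complemented fragment end)
    source: int  # index of the source haplotype
    origin: tuple[int, int]  # fragment interval on the source haplotype


@dataclass(frozen=True)
class ReadSet:
    pairs: tuple[ReadPair, ...]
    read_len: int
    coverage: float
    error_rate: float
    insert_mean: float
    insert_sd: float
    seed: int

    def sequences(self):
        """Yield ``(read_id, sequence)`` for every mate, mate2 as sequenced."""
        for p in self.pairs:
            yield f"{p.read_id}/1", p.seq1
            yield f"{p.read_id}/2", p.seq2

    def __len__(self) -> int:
        return len(self.pairs)


def _add_errors(codes: np.ndarray, error_rate: float, rng: np.random.Generator):
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape)
    return np.where(mask, (codes + shift) % 4, codes)


def simulate_reads(
    haplotypes: list[str], config: ReadConfig | None = None, seed: int = 0
) -> ReadSet:
    """Simulate paired-end reads uniformly over ``haplotypes``.

    Expected pair count per haplotype is ``coverage * len / (2 * read_len)``.
    Substitution errors only; mate2 is sequenced from the reverse strand.
    With ``error_rate=0`` every emitted mate is an exact substring (or exact
    reverse complement of a substring) of its source haplotype.
    """
    cfg = config or ReadConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    for h_idx, hap in enumerate(haplotypes):
        if len(hap) <= cfg.insert_mean:
            raise LocusConfigError(
                f"haplotype {h_idx} shorter than the mean insert size"
            )
        hap_codes = np.frombuffer(hap.encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        hap_codes = lut[hap_codes]
        n_pairs = int(round(cfg.coverage * len(hap) / (2 * cfg.read_len)))
        inserts = np.clip(
            np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)),
            cfg.read_len,
            len(hap),
        ).astype(int)
        starts = rng.integers(0, len(hap) - inserts + 1)
        for k in range(n_pairs):
            s, ins = int(starts[k]), int(inserts[k])
            frag = hap_codes[s : s + ins]
            m1 = _add_errors(frag[: cfg.read_len].copy(), cfg.error_rate, rng)
            m2 = _add_errors(frag[-cfg.read_len :].copy(), cfg.error_rate, rng)
            seq1 = "".join(BASES[c] for c in m1)
            seq2 = revcomp("".join(BASES[c] for c in m2))
            pairs.append(
                ReadPair(
                    read_id=f"h{h_idx}p{k}",
                    seq1=seq1,
                    seq2=seq2,
                    source=h_idx,
                    origin=(s, s + ins),
                )
            )
    return ReadSet(
        pairs=tuple(pairs),
        read_len=cfg.read_len,
        coverage=cfg.coverage,
        error_rate=cfg.error_rate,
        insert_mean=cfg.insert_mean,
        insert_sd=cfg.insert_sd,
        seed=seed,
    )


def tile_reads(sequence: str, read_len: int = 150, step: int = 1) -> list[tuple[str, str]]:
    """Deterministic single-end reads tiling every ``step``-th offset."""
    if read_len <= 0 or step <= 0:
        raise LocusConfigError("read_len and step must be positive")
    return [
        (f"t{s}", sequence[s : s + read_len])
        for s in range(0, len(sequence) - read_len + 1, step)
    ]


# The packaged locus: one fixed synthetic region, analogous to the single
# real genomic locus the pipeline targets.  Read sampling stays seed-driven;
# the locus itself is part of the package definition.
PACKAGED_LOCUS_SEED = 1


def packaged_locus() -> LocusReference:
    return build_locus(LocusConfig(), seed=PACKAGED_LOCUS_SEED)


def locus_with_core(core_len: int, n_divergent: int = 15, seed: int = 0) -> LocusReference:
    """Convenience fixture: default locus geometry with a custom core length."""
    cfg = replace(LocusConfig(), core_len=core_len, n_divergent=n_divergent)
    return build_locus(cfg, seed=seed)
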
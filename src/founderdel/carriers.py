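"""Carrier identification in an imputed, phased panel.

Putative deletion carriers are found either by strict matching of a multi-SNV
tag haplotype (an individual is a het carrier iff exactly one of their two
haplotypes carries the tag allele at *every* tag site) or from the genotype
at a single proxy SNV; calls can then be restricted to individuals whose
proxy-site genotype probability clears a confirmation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .cohort import HaplotypePanel, ImputedPanel


class CarrierInputError(ValueError):
    pass


@dataclass(frozen=True)
class CarrierCallSet:
    """Individuals called as deletion carriers.

    ``ids`` are panel row indices (sorted); ``copy_number`` is the called
    carrier copy number per id (1 het, 2 hom).  Homozygous carriers are
    reported separately and never folded into the het count.
    """

    ids: np.ndarray = field(compare=False)
    copy_number: np.ndarray = field(compare=False)
    panel_size: int
    method: str  # "haplotype" | "snv"
    gp_threshold: float | None = None

    def __post_init__(self):
        assert len(self.ids) == len(self.copy_number)
        assert self.n_het + self.n_hom <= self.panel_size

    @property
    def n_het(self) -> int:
        return int((self.copy_number == 1).sum())

    @property
    def n_hom(self) -> int:
        return int((self.copy_number == 2).sum())

    @property
    def maf(self) -> float:
        return maf_from_carriers(self.n_het, self.panel_size, self.n_hom)

    def id_set(self) -> frozenset[int]:
        return frozenset(int(i) for i in self.ids)


@dataclass(frozen=True)
class ConcordanceReport:
    intersection: tuple[int, ...]
    a_only: tuple[int, ...]
    b_only: tuple[int, ...]
    jaccard: float


def _resolve_sites(panel: HaplotypePanel, sites) -> list[int]:
    idx = []
    for s in sites:
        if isinstance(s, (int, np.integer)):
            if not (0 <= s < panel.n_sites):
                raise CarrierInputError(f"site index {s} not in panel")
            idx.append(int(s))
        else:
            idx.append(panel.site_index(s))  # raises KeyError naming the site
    return idx


def carriers_by_haplotype(
    panel: HaplotypePanel,
    tag_sites: Sequence,
    tag_alleles: Sequence[int],
) -> CarrierCallSet:
    """Strict all-sites haplotype matching: het iff exactly one haplotype
    matches ``tag_alleles`` at all ``tag_sites``, hom iff both do."""
    idx = _resolve_sites(panel, tag_sites)
    if len(idx) != len(tag_alleles):
        raise CarrierInputError("tag_sites and tag_alleles lengths differ")
    alleles = np.asarray(tag_alleles, dtype=panel.haplotypes.dtype)
    match = (panel.haplotypes[:, :, idx] == alleles[None, None, :]).all(axis=2)
    n_match = match.sum(axis=1)
    ids = np.nonzero(n_match > 0)[0]
    return CarrierCallSet(
        ids=ids,
        copy_number=n_match[ids].astype(np.int8),
        panel_size=panel.n_individuals,
        method="haplotype",
    )


def carriers_by_snv(panel: HaplotypePanel, site, allele: int = 1) -> CarrierCallSet:
    """Carrier status from the genotype at a single proxy site."""
    (j,) = _resolve_sites(panel, [site])
    dosage = (panel.haplotypes[:, :, j] == allele).sum(axis=1)
    ids = np.nonzero(dosage > 0)[0]
    return CarrierCallSet(
        ids=ids,
        copy_number=dosage[ids].astype(np.int8),
        panel_size=panel.n_individuals,
        method="snv",
    )


def gp_filter(
    calls: CarrierCallSet,
    panel: ImputedPanel,
    site,
    threshold: float = 0.99,
) -> CarrierCallSet:
    """Retain carriers whose genotype probability at the proxy site exceeds
    ``threshold``.  Never adds individuals; idempotent at a fixed threshold."""
    if getattr(panel, "gp", None) is None:
        raise CarrierInputError("panel carries no genotype probabilities")
    (j,) = _resolve_sites(panel, [site])
    keep = panel.gp[calls.ids, j] > threshold
    return CarrierCallSet(
        ids=calls.ids[keep],
        copy_number=calls.copy_number[keep],
        panel_size=calls.panel_size,
        method=calls.method,
        gp_threshold=threshold,
    )


def maf_from_carriers(n_het: int, N: int, n_hom: int = 0) -> float:
    """Minor-allele frequency implied by carrier counts,
    ``(n_het + 2*n_hom) / (2N)``, rounded half-away-from-zero to 4 decimals."""
    if N <= 0:
        raise CarrierInputError("N must be positive")
    if n_het < 0 or n_hom < 0 or n_het + n_hom > N:
        raise CarrierInputError("carrier counts inconsistent with N")
    raw = (n_het + 2 * n_hom) / (2 * N)
    return float(Decimal(repr(raw)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def concordance(a: CarrierCallSet, b: CarrierCallSet) -> ConcordanceReport:
    """Exact set arithmetic between two call sets on the same panel."""
    if a.panel_size != b.panel_size:
        raise CarrierInputError("call sets come from different panels")
    sa, sb = a.id_set(), b.id_set()
    inter, union = sa & sb, sa | sb
    return ConcordanceReport(
        intersection=tuple(sorted(inter)),
        a_only=tuple(sorted(sa - sb)),
        b_only=tuple(sorted(sb - sa)),
        jaccard=(len(inter) / len(union)) if union else 1.0,
    )
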
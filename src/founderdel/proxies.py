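"""Proxy (tag) SNV discovery for an unobserved founder deletion.

Given diploid genotypes of biallelic-deletion cases plus per-site population
allele frequencies, the chain is: (1) the maximal run of shared homozygosity
around the deletion locus, (2) sites inside it where every case is
homozygous for the minor allele, (3) target/reference-population enrichment,
(4) a match between the SNV's minor-allele frequency and the expected
carrier-derived frequency, and (5) LD r^2 between surviving proxies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd


class ProxyInputError(ValueError):
    pass


@dataclass(frozen=True)
class ProxyCandidate:
    site: str
    position: int
    ref: str
    alt: str
    maf_target: float
    maf_ref: float
    enrichment: float  # maf_target / maf_ref, rounded; math.inf sentinel
    hom_in_all_cases: bool
    in_shared_region: bool


@dataclass(frozen=True)
class LDResult:
    site_a: str
    site_b: str
    D: float
    r2: float


def _round_half_up(x: float, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def enrichment(maf_target: float, maf_ref: float) -> float:
    """Target/reference frequency ratio, rounded half-away-from-zero to two
    decimals.  ``maf_ref = 0`` with a nonzero target yields ``math.inf``
    (absent-in-reference variants are the strongest founder signals); both
    zero yields 1.00 by convention."""
    for v in (maf_target, maf_ref):
        if not (0.0 <= v <= 1.0):
            raise ProxyInputError(f"allele frequency {v} outside [0, 1]")
    if maf_ref == 0.0:
        return math.inf if maf_target > 0 else 1.0
    return _round_half_up(maf_target / maf_ref, 2)


def shared_homozygous_region(
    case_genotypes: np.ndarray,
    anchor: int,
    positions: Sequence[int] | None = None,
) -> tuple[int, int]:
    """Maximal site-index interval containing ``anchor`` where every case is
    homozygous at every site (genotype dosage 0 or 2).  Half-open; empty
    (``(anchor, anchor)``) if some case is heterozygous at the anchor."""
    G = np.asarray(case_genotypes)
    if G.ndim != 2 or G.shape[0] < 1:
        raise ProxyInputError("case_genotypes must be a (cases, sites) array")
    if positions is not None and list(positions) != sorted(positions):
        raise ProxyInputError("sites must be ordered by position")
    if not (0 <= anchor < G.shape[1]):
        raise ProxyInputError("anchor outside site range")
    hom = ((G == 0) | (G == 2)).all(axis=0)
    if not hom[anchor]:
        return anchor, anchor
    lo = anchor
    while lo > 0 and hom[lo - 1]:
        lo -= 1
    hi = anchor + 1
    while hi < G.shape[1] and hom[hi]:
        hi += 1
    return lo, hi


def candidate_proxies(
    case_genotypes: np.ndarray,
    region: tuple[int, int],
    freqs: pd.DataFrame,
) -> list[ProxyCandidate]:
    """Sites inside ``region`` where all cases are homozygous for the minor
    allele, annotated with target/reference enrichment.

    ``freqs`` must carry one row per site, in site order, with columns
    ``site, position, ref, alt, maf_target, maf_ref`` where ``maf_target`` is
    the alt-allele frequency in the target population.  Sites whose target
    alt frequency is >= 0.5 are excluded: homozygosity for the *minor*
    allele presumes the alt allele is the rare one.
    """
    G = np.asarray(case_genotypes)
    lo, hi = region
    if not (0 <= lo <= hi <= G.shape[1]) or len(freqs) != G.shape[1]:
        raise ProxyInputError("region or frequency table does not match the sites")
    out: list[ProxyCandidate] = []
    for j in range(lo, hi):
        row = freqs.iloc[j]
        if row["maf_target"] >= 0.5:
            continue
        hom_minor = bool((G[:, j] == 2).all())
        if not hom_minor:
            continue
        out.append(
            ProxyCandidate(
                site=str(row["site"]),
                position=int(row["position"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                maf_target=float(row["maf_target"]),
                maf_ref=float(row["maf_ref"]),
                enrichment=enrichment(float(row["maf_target"]), float(row["maf_ref"])),
                hom_in_all_cases=True,
                in_shared_region=True,
            )
        )
    return out


def maf_match_filter(
    candidates: Sequence[ProxyCandidate],
    expected_carrier_freq: float,
    rel_tol: float = 0.25,
) -> list[ProxyCandidate]:
    """Keep candidates whose target MAF matches the carrier-derived
    expectation: heterozygous carriers contribute one allele each, so the
    expected tag-SNV MAF is ``expected_carrier_freq / 2`` (the homozygote
    contribution is negligible at founder frequencies)."""
    if not (0.0 < expected_carrier_freq < 0.1):
        raise ProxyInputError("expected_carrier_freq must be in (0, 0.1)")
    expected = expected_carrier_freq / 2.0
    return [
        c
        for c in candidates
        if abs(c.maf_target - expected) / expected <= rel_tol
    ]


def ld_r2(hap_a: np.ndarray, hap_b: np.ndarray, site_a: str = "a", site_b: str = "b") -> LDResult:
    """Two-site LD from phased binary haplotype vectors.

    ``D = f11 - p1*p2`` and ``r2 = D^2 / (p1 q1 p2 q2)``; monomorphic sites
    leave r^2 undefined and raise."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ProxyInputError("haplotype vectors must be equal-length, size >= 2")
    p1, p2 = a.mean(), b.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ProxyInputError("LD undefined: monomorphic site")
    D = float((a * b).mean() - p1 * p2)
    r2 = D * D / (p1 * (1 - p1) * p2 * (1 - p2))
    return LDResult(site_a=site_a, site_b=site_b, D=D, r2=float(r2))


def discover_proxies(
    case_genotypes: np.ndarray,
    freqs: pd.DataFrame,
    anchor: int,
    expected_carrier_freq: float,
    rel_tol: float = 0.25,
) -> tuple[list[ProxyCandidate], tuple[int, int]]:
    """The full discovery chain: shared region -> candidates -> MAF match."""
    region = shared_homozygous_region(
        case_genotypes, anchor, positions=list(freqs["position"])
    )
    cands = candidate_proxies(case_genotypes, region, freqs)
    return maf_match_filter(cands, expected_carrier_freq, rel_tol), region
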
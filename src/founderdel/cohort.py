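"""Cohort-level synthetic data: a founder haplotype carrying the deletion
with tightly linked tag SNVs, imputation noise with per-call genotype
probabilities, region labels, and binary/survival phenotypes.

The founder model is deliberately simple: one ancestral haplotype dropped
into an exchangeable background at frequency ``founder_freq``, then eroded by
``generations`` rounds of recombination -- the probability that a founder
segment stays attached to the deletion through an inter-site interval of
``d`` bp over ``G`` generations is ``(1 - r)^(G*d)``.  This is enough to
produce a tag-SNP/LD structure around the deletion at trivial cost; it makes
no attempt at a faithful demographic history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Site:
    """One biallelic site of the panel.

    ``bg_alt_freq`` is the alt-allele frequency on non-founder haplotypes;
    ``maf_target``/``maf_ref`` are the population annotation frequencies
    carried through to the proxy-discovery frequency table.
    """

    name: str
    position: int
    ref: str
    alt: str
    bg_alt_freq: float
    maf_target: float
    maf_ref: float
    founder_allele: int = 1


# Default site panel: seven tag sites upstream of the deletion anchor, with
# target/reference population frequencies spanning the common-to-rare range a
# founder haplotype drags along.  The two sites closest to the anchor are the
# rare proxies: their alt alleles exist (by default) only on the founder
# haplotype, so their population frequency equals the founder frequency.
DELETION_ANCHOR_POS = 100_000

DEFAULT_SITES: tuple[Site, ...] = (
    Site("site1", DELETION_ANCHOR_POS - 68_932, "A", "G", 0.096, 0.096, 0.081),
    Site("site2", DELETION_ANCHOR_POS - 68_930, "T", "A", 0.110, 0.110, 0.094),
    Site("site3", DELETION_ANCHOR_POS - 58_731, "C", "G", 0.790, 0.790, 0.720),
    Site("site4", DELETION_ANCHOR_POS - 53_829, "C", "G", 0.380, 0.380, 0.310),
    Site("site5", DELETION_ANCHOR_POS - 19_021, "C", "T", 0.320, 0.320, 0.300),
    Site("proxy1", DELETION_ANCHOR_POS - 4_927, "T", "G", 0.0, 0.0032, 0.000029),
    Site("proxy2", DELETION_ANCHOR_POS - 333, "G", "C", 0.0, 0.0031, 0.000030),
)

PROXY_SITE_NAMES = ("proxy1", "proxy2")


@dataclass(frozen=True)
class PanelConfig:
    N: int = 500_000
    sites: tuple[Site, ...] = DEFAULT_SITES
    founder_freq: float = 0.00214  # haplotype (allele) frequency of the founder
    generations: int = 20
    recomb_rate: float = 1e-8  # per bp per generation
    anchor_pos: int = DELETION_ANCHOR_POS

    def validate(self) -> None:
        if not (0.0 <= self.founder_freq < 0.5):
            raise CohortConfigError("founder_freq must be in [0, 0.5)")
        if len(self.sites) < 5:
            raise CohortConfigError("n_sites must be >= 5")
        if self.N <= 0 or self.generations < 0 or self.recomb_rate < 0:
            raise CohortConfigError("N, generations, recomb_rate must be valid")
        pos = [s.position for s in self.sites]
        if pos != sorted(pos):
            raise CohortConfigError("sites must be ordered by position")


@dataclass
class HaplotypePanel:
    """Phased genotypes over ``sites`` with per-individual deletion truth.

    ``haplotypes`` has shape ``(N, 2, S)`` with values 0/1; ``carrier_truth``
    is the per-individual deletion copy number.
    """

    haplotypes: np.ndarray
    sites: tuple[Site, ...]
    carrier_truth: np.ndarray
    founder_block: tuple[int, int]
    config: PanelConfig | None = None
    founder_haplotypes: np.ndarray | None = None  # (N, 2) bool truth, if known

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[2]

    def site_index(self, name: str) -> int:
        for i, s in enumerate(self.sites):
            if s.name == name:
                return i
        raise KeyError(f"site {name!r} not in panel")

    def dosage(self, site: "int | str") -> np.ndarray:
        j = site if isinstance(site, int) else self.site_index(site)
        return self.haplotypes[:, :, j].sum(axis=1)

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass
class ImputedPanel(HaplotypePanel):
    """A panel after simulated imputation: possibly flipped alleles plus a
    per-individual-per-site genotype probability in [0, 1]."""

    gp: np.ndarray = field(default=None)  # shape (N, S)
    error_rate: float = 0.0


def simulate_panel(config: PanelConfig | None = None, seed: int = 0) -> HaplotypePanel:
    """Forward-simulate the phased panel; deterministic per ``(config, seed)``."""
    cfg = config or PanelConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    N, S = cfg.N, len(cfg.sites)
    bg = np.array([s.bg_alt_freq for s in cfg.sites])
    H = (rng.random((N, 2, S)) < bg).astype(np.int8)

    founder = rng.random((N, 2)) < cfg.founder_freq
    nf = int(founder.sum())
    if nf:
        retained = _founder_retention(cfg, nf, rng)  # (nf, S) bool
        fa = np.array([s.founder_allele for s in cfg.sites], dtype=np.int8)
        fresh = (rng.random((nf, S)) < bg).astype(np.int8)
        block = np.where(retained, fa[None, :], fresh)
        H[founder.nonzero()[0], founder.nonzero()[1], :] = block
    carrier_truth = founder.sum(axis=1).astype(np.int8)
    return HaplotypePanel(
        haplotypes=H,
        sites=cfg.sites,
        carrier_truth=carrier_truth,
        founder_block=(0, S),
        config=cfg,
        founder_haplotypes=founder,
    )


def _founder_retention(cfg: PanelConfig, nf: int, rng: np.random.Generator) -> np.ndarray:
    """Per founder haplotype, which sites still carry the founder allele.

    Sites on each side of the anchor are ordered by distance; a site is
    retained iff every inter-site interval between it and the anchor survived
    all ``generations`` meioses un-recombined.
    """
    S = len(cfg.sites)
    retained = np.ones((nf, S), dtype=bool)
    pos = np.array([s.position for s in cfg.sites])
    for side_mask in (pos <= cfg.anchor_pos, pos > cfg.anchor_pos):
        idx = np.nonzero(side_mask)[0]
        if idx.size == 0:
            continue
        d = np.abs(pos[idx] - cfg.anchor_pos)
        order = idx[np.argsort(d)]
        dist_sorted = np.sort(d)
        gaps = np.diff(np.concatenate([[0], dist_sorted]))
        p_intact = (1.0 - cfg.recomb_rate) ** (cfg.generations * gaps)
        intact = rng.random((nf, len(order))) < p_intact[None, :]
        keep = np.cumprod(intact, axis=1).astype(bool)
        retained[:, order] = keep
    return retained


def add_imputation_noise(
    panel: HaplotypePanel,
    error_rate: float = 0.0,
    seed: int = 0,
    gp_correct_beta: tuple[float, float] = (1.0, 99.0),
    gp_wrong_range: tuple[float, float] = (0.4, 0.9),
) -> ImputedPanel:
    """Flip each haplotype allele independently with ``error_rate``; draw GP
    so that incorrect genotype calls have visibly lower confidence.

    Correct calls get ``GP ~ 1 - Beta(1, 99)`` (mean about 0.99); calls where
    either allele flipped get ``GP ~ Uniform(0.4, 0.9)``.  This mimics the
    qualitative behaviour of imputation confidence, not any panel's actual
    error structure.
    """
    if not (0.0 <= error_rate < 0.5):
        raise CohortConfigError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    H = panel.haplotypes.copy()
    if error_rate > 0:
        flips = rng.random(H.shape) < error_rate
        H ^= flips.astype(np.int8)
        wrong = flips.any(axis=1)
    else:
        wrong = np.zeros((panel.n_individuals, panel.n_sites), dtype=bool)
    gp = 1.0 - rng.beta(*gp_correct_beta, size=wrong.shape)
    if error_rate > 0:
        gp_bad = rng.uniform(*gp_wrong_range, size=wrong.shape)
        gp = np.where(wrong, gp_bad, gp)
    return ImputedPanel(
        haplotypes=H,
        sites=panel.sites,
        carrier_truth=panel.carrier_truth,
        founder_block=panel.founder_block,
        config=panel.config,
        founder_haplotypes=panel.founder_haplotypes,
        gp=gp,
        error_rate=error_rate,
    )


def sample_case_genotypes(
    config: PanelConfig | None = None, n_cases: int = 3, seed: int = 0
) -> np.ndarray:
    """Diploid genotypes (alt-allele dosage, shape ``(n_cases, S)``) of
    biallelic deletion carriers: each case carries two founder haplotypes,
    independently eroded by recombination."""
    cfg = config or PanelConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    S = len(cfg.sites)
    bg = np.array([s.bg_alt_freq for s in cfg.sites])
    retained = _founder_retention(cfg, 2 * n_cases, rng)
    fa = np.array([s.founder_allele for s in cfg.sites], dtype=np.int8)
    fresh = (rng.random((2 * n_cases, S)) < bg).astype(np.int8)
    haps = np.where(retained, fa[None, :], fresh)
    return haps.reshape(n_cases, 2, S).sum(axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class SurvivalSpec:
    """Generative model for endpoints and ages at onset.

    Event times are exponential with individual hazard
    ``baseline_hazard * prod(HR_c ** x_c)`` starting at ``entry_age``, with
    administrative censoring after ``censor_horizon`` years.  Binary
    endpoints are drawn from a logistic model with the configured per-
    endpoint odds ratios applied to the carrier dosage.
    """

    baseline_hazard: float = 0.002  # events / person-year
    hr_map: Mapping[str, float] = field(
        default_factory=lambda: {"carrier": 2.14, "apoe_e4": 2.30, "sex": 1.13}
    )
    censor_horizon: float = 60.0  # years of follow-up
    entry_age: float = 40.0
    or_map: Mapping[str, float] = field(default_factory=dict)
    endpoint_baseline_prev: float = 0.05

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise CohortConfigError("baseline hazard must be positive")
        if any(v <= 0 for v in self.hr_map.values()):
            raise CohortConfigError("hazard ratios must be positive")
        if any(v <= 0 for v in self.or_map.values()):
            raise CohortConfigError("odds ratios must be positive")
        if self.censor_horizon < 0:
            raise CohortConfigError("censor horizon must be non-negative")


def default_endpoint_map(
    n_endpoints: int = 50,
    causal: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """A phenome-scan-sized endpoint map: a few causal endpoints plus nulls."""
    causal = dict(causal) if causal is not None else {"dementia": 2.1, "alzheimer": 2.1}
    out = dict(causal)
    k = 1
    while len(out) < n_endpoints:
        name = f"null{k:03d}"
        if name not in out:
            out[name] = 1.0
        k += 1
    return out


def simulate_phenotypes(
    carrier_dosage: "np.ndarray | HaplotypePanel",
    spec: SurvivalSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate covariates, binary endpoints, and a survival outcome.

    Returns one row per individual with columns ``carrier`` (deletion
    dosage), ``sex``, ``apoe_e4``, one 0/1 column per endpoint in
    ``spec.or_map``, plus ``age`` (onset age for events, censoring age
    otherwise) and ``event``.
    """
    sp = spec or SurvivalSpec()
    sp.validate()
    if isinstance(carrier_dosage, HaplotypePanel):
        dosage = carrier_dosage.carrier_truth.astype(float)
    else:
        dosage = np.asarray(carrier_dosage, dtype=float)
    rng = np.random.default_rng(seed)
    N = dosage.shape[0]
    sex = (rng.random(N) < 0.5).astype(np.int8)
    apoe = (rng.random(N) < 0.3).astype(np.int8)
    covars = {"carrier": dosage, "sex": sex, "apoe_e4": apoe}

    log_h = np.log(sp.baseline_hazard) * np.ones(N)
    for name, hr in sp.hr_map.items():
        if name not in covars:
            raise CohortConfigError(f"hr_map refers to unknown covariate {name!r}")
        log_h += np.log(hr) * covars[name]
    t = rng.exponential(1.0, size=N) / np.exp(log_h)
    event = t <= sp.censor_horizon
    age = sp.entry_age + np.minimum(t, sp.censor_horizon)

    data = {
        "carrier": dosage.astype(np.int8),
        "sex": sex,
        "apoe_e4": apoe,
        "age": age,
        "event": event.astype(np.int8),
    }
    if sp.or_map:
        from scipy.special import expit, logit

        base = logit(sp.endpoint_baseline_prev)
        for name, or_ in sp.or_map.items():
            p = expit(base + np.log(or_) * dosage)
            data[name] = (rng.random(N) < p).astype(np.int8)
    return pd.DataFrame(data)


def assign_regions(
    N: int,
    region_freq_map: Mapping[str, float],
    seed: int = 0,
    carrier_flags: np.ndarray | None = None,
    region_maf_map: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Multinomial region-of-birth labels; optionally concentrate carriers.

    With ``carrier_flags`` and ``region_maf_map`` given, carriers are placed
    with probability proportional to ``region_size * region_maf``, producing
    the configured regional allele-frequency contrasts in expectation.
    """
    names = list(region_freq_map)
    freqs = np.array([region_freq_map[k] for k in names], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise CohortConfigError("region frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(np.array(names, dtype=object), size=N, p=freqs)
    if carrier_flags is not None and region_maf_map is not None:
        w = freqs * np.array([region_maf_map[k] for k in names])
        w = w / w.sum()
        idx = np.nonzero(np.asarray(carrier_flags) > 0)[0]
        labels[idx] = rng.choice(np.array(names, dtype=object), size=idx.size, p=w)
    return labels


def panel_frequency_table(panel: HaplotypePanel, empirical: bool = True) -> pd.DataFrame:
    """Per-site frequency table for proxy discovery.

    ``empirical=True`` uses the realized target-population allele frequencies
    of the simulated panel (what a biobank would actually observe);
    otherwise the configured annotation frequencies.
    """
    af = panel.allele_freqs()
    rows = []
    for j, s in enumerate(panel.sites):
        target = float(af[j]) if empirical else s.maf_target
        rows.append(
            {
                "site": s.name,
                "position": s.position,
                "ref": s.ref,
                "alt": s.alt,
                "maf_target": min(target, 1.0 - target) if empirical else target,
                "maf_ref": s.maf_ref,
            }
        )
    return pd.DataFrame(rows)


def with_off_background_proxy(
    config: PanelConfig | None = None, rate: float = 1e-4
) -> PanelConfig:
    """A panel config where the nearest proxy allele also occurs off the
    founder background at ``rate`` -- the structural analogue of a tag SNV
    that is an imperfect proxy (single-SNV calls gain extra individuals)."""
    cfg = config or PanelConfig()
    sites = tuple(
        replace(s, bg_alt_freq=rate) if s.name == "proxy1" else s for s in cfg.sites
    )
    return replace(cfg, sites=sites)
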
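"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ go through Biopython, VCF through pysam.  The VCF dialect is a
strict minimal subset of VCF 4.2: biallelic records, phased ``GT`` (``a|b``),
and an optional single-valued ``GP`` FORMAT field carrying the per-call
genotype probability.  Positions are 1-based in files and 0-based in memory.

Output writers are deterministic: fixed column order, fixed float formats,
so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .carriers import CarrierCallSet
from .cohort import HaplotypePanel, ImputedPanel, PanelConfig, Site, SurvivalSpec
from .locus import LocusConfig, LocusReference, ReadConfig, ReadSet
from .proxies import ProxyCandidate
from .stats import AssocResult, CoxFit, KMCurve

SCHEMA_VERSION = 1


class VcfParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(readset: ReadSet, prefix) -> tuple[Path, Path]:
    """Paired FASTQ (Phred+33, constant quality 'I') as ``<prefix>_1/2.fastq``."""
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    for path, mate in ((p1, 1), (p2, 2)):
        with open(path, "w") as fh:
            for pair in readset.pairs:
                seq = pair.seq1 if mate == 1 else pair.seq2
                fh.write(f"@{pair.read_id}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    return p1, p2


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# VCF


def write_vcf(panel: HaplotypePanel, path, contig: str = "chr19") -> None:
    """Minimal phased VCF 4.2 with per-call GP when the panel is imputed."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    max_pos = max(s.position for s in panel.sites) + 10_000
    header.contigs.add(contig, length=max_pos)
    header.formats.add("GT", 1, "String", "Phased genotype")
    has_gp = isinstance(panel, ImputedPanel) and panel.gp is not None
    if has_gp:
        header.formats.add("GP", 1, "Float", "Genotype probability of the call")
    samples = [f"S{i:06d}" for i in range(panel.n_individuals)]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, site in enumerate(panel.sites):
            rec = vcf.new_record(
                contig=contig,
                start=site.position,  # pysam start is 0-based; POS printed 1-based
                alleles=(site.ref, site.alt),
                id=site.name,
            )
            H = panel.haplotypes[:, :, j]
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = (int(H[i, 0]), int(H[i, 1]))
                rec.samples[s].phased = True
                if has_gp:
                    rec.samples[s]["GP"] = float(panel.gp[i, j])
            vcf.write(rec)


def read_vcf(path, require_phased: bool = True) -> ImputedPanel:
    """Read a minimal phased VCF into a panel (carrier truth unknown).

    Unphased genotypes raise when ``require_phased`` -- haplotype matching
    needs phase.  Missing GP defaults to 1.0.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    sites: list[Site] = []
    hap_cols: list[np.ndarray] = []
    gp_cols: list[np.ndarray] = []
    samples = list(vcf.header.samples)
    for line_no, rec in enumerate(vcf, start=1):
        if rec.alts is None or len(rec.alts) != 1:
            raise VcfParseError(
                f"record {line_no} ({rec.chrom}:{rec.pos}): exactly one ALT required"
            )
        sites.append(
            Site(
                name=rec.id or f"{rec.chrom}:{rec.pos}",
                position=rec.start,
                ref=rec.ref,
                alt=rec.alts[0],
                bg_alt_freq=0.0,
                maf_target=float("nan"),
                maf_ref=float("nan"),
            )
        )
        col = np.zeros((len(samples), 2), dtype=np.int8)
        gp = np.ones(len(samples))
        for i, s in enumerate(samples):
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or None in gt:
                raise VcfParseError(
                    f"record {line_no}: missing genotype for sample {s}"
                )
            if require_phased and not call.phased:
                raise VcfParseError(
                    f"record {line_no}: unphased genotype for sample {s}; "
                    "phased GT (a|b) required"
                )
            col[i] = gt
            if "GP" in call and call["GP"] is not None:
                gp[i] = float(call["GP"])
        hap_cols.append(col)
        gp_cols.append(gp)
    if not sites:
        raise VcfParseError(f"no records in {path}")
    H = np.stack(hap_cols, axis=2)
    return ImputedPanel(
        haplotypes=H,
        sites=tuple(sites),
        carrier_truth=None,
        founder_block=(0, len(sites)),
        config=None,
        gp=np.stack(gp_cols, axis=1),
        error_rate=float("nan"),
    )


# ---------------------------------------------------------------------------
# TSV / JSON writers


def _fmt(x: float, nd: int = 6) -> str:
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.{nd}g}" if isinstance(x, float) else str(x)


def write_proxy_table(candidates: Sequence[ProxyCandidate], path) -> None:
    """Tag-haplotype report: one row per candidate SNV with population
    frequencies and enrichment, infinite enrichment sorted last."""
    rows = sorted(
        candidates, key=lambda c: (math.isinf(c.enrichment), c.position)
    )
    df = pd.DataFrame(
        [
            {
                "rsID": c.site,
                "position": c.position + 1,  # 1-based in reports
                "alleles": f"{c.ref}>{c.alt}",
                "maf_target": c.maf_target,
                "maf_ref": c.maf_ref,
                "enrichment": c.enrichment,
                "hom_in_all_cases": int(c.hom_in_all_cases),
                "in_shared_region": int(c.in_shared_region),
            }
            for c in rows
        ],
        columns=[
            "rsID", "position", "alleles", "maf_target", "maf_ref",
            "enrichment", "hom_in_all_cases", "in_shared_region",
        ],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_phewas_tsv(results: Sequence[AssocResult], path) -> None:
    df = pd.DataFrame(
        [
            {
                "endpoint": r.endpoint,
                "beta": r.beta,
                "OR": r.or_,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p": r.p,
                "af_case": r.af_case,
                "af_control": r.af_control,
                "converged": int(r.converged),
                "genome_wide_significant": int(r.genome_wide_significant),
            }
            for r in results
        ],
        columns=[
            "endpoint", "beta", "OR", "ci_low", "ci_high", "p",
            "af_case", "af_control", "converged", "genome_wide_significant",
        ],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_km_tsv(curves: "Mapping[str, KMCurve] | KMCurve", path) -> None:
    if isinstance(curves, KMCurve):
        curves = {curves.group or "all": curves}
    rows = []
    for label in sorted(curves):
        c = curves[label]
        for t, n, d, s in zip(c.times, c.at_risk, c.n_events, c.survival):
            rows.append(
                {"group": label, "time": t, "at_risk": int(n),
                 "events": int(d), "survival": s}
            )
    pd.DataFrame(rows, columns=["group", "time", "at_risk", "events", "survival"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_cox_tsv(fit: CoxFit, path) -> None:
    fit.summary().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_carrier_calls(calls: CarrierCallSet, dir_path, stem: str = "carriers") -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"individual": calls.ids, "copy_number": calls.copy_number}
    ).to_csv(d / f"{stem}.tsv", sep="\t", index=False)
    write_json_summary(
        {
            "n_het": calls.n_het,
            "n_hom": calls.n_hom,
            "panel_size": calls.panel_size,
            "maf": calls.maf,
            "method": calls.method,
            "gp_threshold": calls.gp_threshold,
        },
        d / f"{stem}.json",
    )


def write_json_summary(payload: Mapping, path) -> None:
    out = {"schema_version": SCHEMA_VERSION}
    out.update(payload)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Hierarchical run configuration; every stochastic stage draws its seed
    from here and every threshold in the pipeline is overridable."""

    seed: int = 0
    locus: LocusConfig = dataclasses.field(default_factory=LocusConfig)
    reads: ReadConfig = dataclasses.field(default_factory=ReadConfig)
    cohort: PanelConfig = dataclasses.field(default_factory=PanelConfig)
    survival: SurvivalSpec = dataclasses.field(default_factory=SurvivalSpec)
    imputation_error_rate: float = 0.0
    gp_threshold: float = 0.99
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        if "locus" in d:
            kwargs["locus"] = LocusConfig(**d.pop("locus"))
        if "reads" in d:
            kwargs["reads"] = ReadConfig(**d.pop("reads"))
        if "cohort" in d:
            c = dict(d.pop("cohort"))
            if "sites" in c:
                c["sites"] = tuple(Site(**s) for s in c["sites"])
            kwargs["cohort"] = PanelConfig(**c)
        if "survival" in d:
            s = dict(d.pop("survival"))
            kwargs["survival"] = SurvivalSpec(**s)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def locus_truth_sidecar(ref: LocusReference, path) -> None:
    """JSON sidecar with the planted truth of a simulated locus."""
    write_json_summary(
        {
            "repeat_a_span": ref.repeat_a_span,
            "repeat_b_span": ref.repeat_b_span,
            "divergent_positions": list(ref.divergent_positions),
            "core_span": ref.core_span,
            "exon_spans": [list(e) for e in ref.exon_spans],
            "deletion_span": ref.deletion_span,
        },
        path,
    )
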
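"""Readers and writers for the toolkit's on-disk formats.

Reference goes out as FASTA (via Biopython), the panel as a 5-column BED
(chrom, start, end, gene_id, tier), truth sets and calls as uncompressed
VCF 4.2, coverage and chimeric evidence as TSV (via pandas). Every writer
embeds a provenance header (tool version and, where meaningful, the seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import panelval
from panelval.cnv import CnvCall
from panelval.errors import ParameterError
from panelval.fusion import FusionCall
from panelval.somatic import VariantCall
from panelval.synthetic import (
    ChimericEvidence,
    GeneAnnotation,
    GeneCoverage,
    SiteCounts,
    ToyReference,
    TruthVariant,
)

__all__ = [
    "write_reference_fasta",
    "read_reference_fasta",
    "write_panel_bed",
    "read_panel_bed",
    "write_truth_vcf",
    "write_calls_vcf",
    "read_vcf_records",
    "write_site_counts_tsv",
    "read_site_counts_tsv",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "write_chimeric_tsv",
    "read_chimeric_tsv",
    "write_cnv_calls_tsv",
    "write_fusion_calls_tsv",
    "write_json_report",
]


# -- FASTA / BED -------------------------------------------------------------


def write_reference_fasta(reference: ToyReference, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=f"panelval={panelval.__version__} seed={reference.seed}")
        for name, seq in reference.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_panel_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.tier}\n")


def read_panel_bed(path: str | Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParameterError(f"BED line has {len(fields)} fields, need 5: {line!r}")
            genes.append(
                GeneAnnotation(
                    contig=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    gene_id=fields[3],
                    tier=int(fields[4]),
                )
            )
    return genes


# -- VCF ---------------------------------------------------------------------


def _vcf_header(reference: ToyReference | None, extra_meta: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.2", f"##source=panelval-{panelval.__version__}"]
    lines.extend(extra_meta)
    if reference is not None:
        for name, seq in reference.contigs.items():
            lines.append(f"##contig=<ID={name},length={len(seq)}>")
    return "\n".join(lines)


def write_truth_vcf(
    truths: Sequence[TruthVariant],
    path: str | Path,
    reference: ToyReference | None = None,
    seed: int | None = None,
) -> None:
    meta = [
        '##INFO=<ID=TRUE_VAF,Number=1,Type=Float,Description="Inserted allele fraction">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Known classification">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">',
        '##INFO=<ID=VTYPE,Number=1,Type=String,Description="SNV/INS/DEL">',
    ]
    if seed is not None:
        meta.append(f"##panelval_seed={seed}")
    with open(path, "w") as fh:
        fh.write(_vcf_header(reference, meta) + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(truths, key=lambda v: (v.contig, v.pos, v.alt_allele)):
            info = (
                f"TRUE_VAF={v.true_vaf:g};CLASS={v.classification};"
                f"GENE={v.gene_id};VTYPE={v.vtype}"
            )
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t{info}\n"
            )


def write_calls_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    reference: ToyReference | None = None,
) -> None:
    meta = [
        '##FILTER=<ID=LOW_DEPTH,Description="Tumor depth below minimum locus depth">',
        '##FILTER=<ID=GERMLINE,Description="Allele present in matched normal">',
        '##FILTER=<ID=BENIGN,Description="Known benign classification">',
        '##FILTER=<ID=BELOW_LOD,Description="Observed VAF below tier limit of detection">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">',
        '##INFO=<ID=TIER,Number=1,Type=Integer,Description="Panel tier">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
    ]
    with open(path, "w") as fh:
        fh.write(_vcf_header(reference, meta) + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.alt_allele)):
            filt = "PASS" if c.reported else ";".join(sorted(c.filters))
            ref_count = c.depth - c.alt_count
            fh.write(
                f"{c.contig}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\t{filt}\t"
                f"GENE={c.gene_id};TIER={c.tier}\tDP:AD:AF\t"
                f"{c.depth}:{ref_count},{c.alt_count}:{c.vaf:.4f}\n"
            )


def read_vcf_records(path: str | Path) -> list[dict]:
    """Minimal VCF reader returning dicts (chrom, pos, ref, alt, filter, info)."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = {}
            for item in f[7].split(";"):
                if "=" in item:
                    k, val = item.split("=", 1)
                    info[k] = val
                elif item and item != ".":
                    info[item] = True
            records.append(
                {
                    "chrom": f[0],
                    "pos": int(f[1]),
                    "ref": f[3],
                    "alt": f[4],
                    "filter": f[6],
                    "info": info,
                }
            )
    return records


# -- TSV tables --------------------------------------------------------------


def write_site_counts_tsv(sites: Sequence[SiteCounts], path: str | Path) -> None:
    rows = [
        {
            "contig": s.contig,
            "pos": s.pos,
            "depth": s.depth,
            "ref": s.ref,
            "allele_counts": json.dumps(s.allele_counts, sort_keys=True),
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_site_counts_tsv(path: str | Path) -> list[SiteCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str})
    return [
        SiteCounts(
            contig=str(r.contig),
            pos=int(r.pos),
            depth=int(r.depth),
            allele_counts={k: int(v) for k, v in json.loads(r.allele_counts).items()},
            ref=str(r.ref),
        )
        for r in df.itertuples()
    ]


def write_coverage_tsv(coverage: Sequence[GeneCoverage], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "mean_depth": g.mean_depth, "sample_id": g.sample_id}
            for g in coverage
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_coverage_tsv(path: str | Path) -> list[GeneCoverage]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneCoverage(
            gene_id=str(r.gene_id),
            mean_depth=float(r.mean_depth),
            sample_id=str(getattr(r, "sample_id", "")),
        )
        for r in df.itertuples()
    ]


def write_chimeric_tsv(evidence: Sequence[ChimericEvidence], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene5": e.gene5,
                "gene3": e.gene3,
                "n_spanning": e.n_spanning,
                "n_discordant": e.n_discordant,
            }
            for e in evidence
        ]
    ).to_csv(path, sep="\t", index=False)


def read_chimeric_tsv(path: str | Path) -> list[ChimericEvidence]:
    df = pd.read_csv(path, sep="\t")
    return [
        ChimericEvidence(
            gene5=str(r.gene5),
            gene3=str(r.gene3),
            n_spanning=int(r.n_spanning),
            n_discordant=int(r.n_discordant),
        )
        for r in df.itertuples()
    ]


def write_cnv_calls_tsv(calls: Sequence[CnvCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "ratio": round(c.ratio, 4),
                "estimated_copies": round(c.estimated_copies, 3),
                "verdict": c.verdict,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_fusion_calls_tsv(calls: Sequence[FusionCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene5": c.gene5,
                "gene3": c.gene3,
                "n_spanning": c.n_spanning,
                "n_discordant": c.n_discordant,
                "tier": c.tier,
                "reported": c.reported,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_json_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
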
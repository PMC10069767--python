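"""File I/O: FASTA, BED, depth TSV, minimal GT-only VCF, samples TSV.

Interval conventions: in-memory coordinates are 1-based with inclusive
starts and exclusive ends; BED output converts to 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .depthdeconv import DepthTrack, RegionCall, WindowTrack
from .sweepscan import MISSING, GenotypeMatrix

__all__ = [
    "write_fasta",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_truth_bed",
    "write_window_tsv",
    "write_regions",
    "write_vcf",
    "read_vcf",
    "write_samples_tsv",
    "read_samples_tsv",
]

_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
_CODE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def write_depth_tsv(track: DepthTrack, path) -> None:
    """Two-column TSV: 1-based position, per-base depth."""
    pd.DataFrame(
        {"pos": np.arange(1, len(track) + 1), "depth": track.depth}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_depth_tsv(path, genome_id: str | None = None) -> DepthTrack:
    """Read a 2-column (pos, depth) or 3-column (genome_id, pos, depth) TSV.

    Positions must be 1..L contiguous (per-base track)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        genome_id = genome_id or str(df.iloc[0, 0])
        df = df.iloc[:, 1:3]
    pos = df.iloc[:, 0].to_numpy(dtype=int)
    if not np.array_equal(pos, np.arange(1, pos.size + 1)):
        raise ValueError("depth TSV must cover positions 1..L contiguously")
    return DepthTrack(
        genome_id=genome_id or "genome", depth=df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_truth_bed(truth: pd.DataFrame, path, name_col: str = "kind") -> None:
    """Truth intervals as 3+1-column BED (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": "strainA",
            "start": truth["start"] - 1,
            "end": truth["end"] - 1,
            "name": truth[name_col],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_window_tsv(wt: WindowTrack, path) -> None:
    wt.windows.to_csv(path, sep="\t", index=False)


def write_regions(regions: list[RegionCall], bed_path, json_path=None,
                  chrom: str = "genome") -> None:
    """Region calls as BED plus an optional JSON sidecar with labels and
    rationale (intervals here are inclusive bp spans)."""
    rows = [
        {"chrom": chrom, "start": r.start - 1, "end": r.end, "name": r.label
         or r.direction}
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", header=False, index=False)
    if json_path is not None:
        payload = [
            {
                "start": r.start, "end": r.end,
                "mean_norm_depth": r.mean_norm_depth, "n_windows": r.n_windows,
                "direction": r.direction, "label": r.label,
                "rationale": r.rationale,
            }
            for r in regions
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2))


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal biallelic GT-only VCF."""
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for contig in gm.sites["contig"].unique():
        length = int(gm.sites.loc[gm.sites["contig"] == contig, "pos"].max()) + 1
        lines.append(f"##contig=<ID={contig},length={length}>")
    samples = gm.samples["sample_id"].tolist()
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for j, row in enumerate(gm.sites.itertuples()):
        gts = "\t".join(_CODE_GT[int(g)] for g in gm.genotypes[:, j])
        lines.append(
            f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(vcf_path, samples_path=None) -> GenotypeMatrix:
    """Read a GT-only VCF (plain text) plus an optional samples TSV.

    Multi-allelic records are rejected: the analyses assume biallelic SNPs.
    """
    with pysam.VariantFile(str(vcf_path)) as vf:
        sample_ids = list(vf.header.samples)
        site_rows, geno_cols = [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "only biallelic SNPs are supported"
                )
            site_rows.append(
                {"contig": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                 "alt": rec.alts[0]}
            )
            col = []
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(MISSING)
                else:
                    col.append(_GT_CODE[tuple(sorted(gt))])
            geno_cols.append(col)
    genotypes = np.array(geno_cols, dtype=np.int8).T
    if samples_path is not None:
        samples = read_samples_tsv(samples_path)
        samples = samples.set_index("sample_id").loc[sample_ids].reset_index()
    else:
        samples = pd.DataFrame(
            {"sample_id": sample_ids, "line": "NA", "phenotype": "NA"}
        )
    return GenotypeMatrix(
        genotypes=genotypes, sites=pd.DataFrame(site_rows), samples=samples
    )


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "line", "phenotype"}
    if not required <= set(df.columns):
        raise ValueError(f"samples TSV needs columns {sorted(required)}")
    return df
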
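"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as VCF (two parents plus one sample per RIL; read
back through cyvcf2) or as a plain TSV matrix of A/B/H/- characters;
phenotypes as long-format TSV; bin and map tables as CSV; simulation truth as
a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BinMatrix,
    GenotypeMatrix,
    chars_to_codes,
    codes_to_chars,
)
from .filtering import RawCalls

_DOSE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_CODE_TO_GT = ["0/0", "1/1", "0/1", "./."]  # A, B, H, missing


def write_vcf(path, gm: GenotypeMatrix, parent_names=("P1", "P2")) -> None:
    """Write coded genotypes as a minimal VCF; the maternal allele is REF.

    Parents are emitted as the first two samples, homozygous REF and ALT.
    """
    path = Path(path)
    samples = list(parent_names) + list(gm.lines)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.chroms():
            pos, _ = gm.for_chrom(chrom)
            fh.write(f"##contig=<ID={chrom},length={int(pos.max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        chroms = gm.sites["chrom"].to_numpy()
        positions = gm.sites["pos"].to_numpy()
        for i in range(gm.n_sites):
            gts = [_CODE_TO_GT[c] for c in gm.codes[i]]
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, parent_names=("P1", "P2")) -> RawCalls:
    """Read a biallelic VCF into alt-allele doses with the two parents split out."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in parent_names:
        if p not in samples:
            raise ValueError(f"parent sample {p!r} not found in VCF")
    p_idx = [samples.index(p) for p in parent_names]
    line_idx = [i for i in range(len(samples)) if i not in p_idx]
    rows, doses = [], []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    remap = np.array([0, 1, -1, 2], dtype=np.int8)
    for v in vcf:
        rows.append((int(v.CHROM), v.POS))
        doses.append(remap[v.gt_types])
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    doses = np.asarray(doses, dtype=np.int8)
    return RawCalls(
        sites=sites,
        doses=doses[:, line_idx],
        parent1=doses[:, p_idx[0]],
        parent2=doses[:, p_idx[1]],
        lines=[samples[i] for i in line_idx],
    )


def write_genotype_tsv(path, gm: GenotypeMatrix) -> None:
    chars = pd.DataFrame(codes_to_chars(gm.codes), columns=list(gm.lines))
    df = pd.concat([gm.sites.reset_index(drop=True), chars], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    lines = [c for c in df.columns if c not in ("chrom", "pos")]
    codes = chars_to_codes(df[lines].to_numpy(dtype=str))
    return GenotypeMatrix(sites=df[["chrom", "pos"]], codes=codes.astype(np.int8), lines=lines)


def write_bin_csv(path, bm: BinMatrix) -> None:
    chars = pd.DataFrame(codes_to_chars(bm.codes), columns=list(bm.lines))
    df = pd.concat([bm.bins[["chrom", "name", "start", "end"]].reset_index(drop=True), chars], axis=1)
    df.to_csv(path, index=False)


def read_bin_csv(path) -> BinMatrix:
    df = pd.read_csv(path)
    lines = [c for c in df.columns if c not in ("chrom", "name", "start", "end")]
    codes = chars_to_codes(df[lines].to_numpy(dtype=str)).astype(np.int8)
    bins = df[["chrom", "name", "start", "end"]].copy()
    bins["index"] = bins.groupby("chrom").cumcount() + 1
    return BinMatrix(bins=bins[["chrom", "start", "end", "index", "name"]], codes=codes, lines=lines)


def write_phenotypes_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
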
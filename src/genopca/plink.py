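"""PLINK 1 binary (.bed/.bim/.fam) input and output.

The .bed layout is the 3-byte header 0x6C 0x1B 0x01 (SNP-major) followed by
ceil(n/4) bytes per SNP, two bits per sample, least-significant pair first.
The 2-bit codes map to allele1 (A1) dosage as

    00 -> 2 (hom A1)    01 -> missing    10 -> 1 (het)    11 -> 0 (hom A2)

so the decoded dosage counts copies of allele1, which PLINK places the minor
allele in by convention.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .genotypes import GenotypeMatrix, snp_metadata

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
_MISSING_SENTINEL = 3  # internal code while decoding

# 256 x 4 lookup: byte -> four dosage codes (0,1,2 or 3=missing), LSB pair first
_DECODE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        two = (_b >> (2 * _k)) & 0b11
        _DECODE[_b, _k] = {0b00: 2, 0b01: _MISSING_SENTINEL, 0b10: 1, 0b11: 0}[two]
_ENCODE = np.array([0b11, 0b10, 0b00, 0b01], dtype=np.uint8)  # dosage/missing -> bits


def _paths(prefix_or_bed) -> tuple[Path, Path, Path]:
    p = Path(prefix_or_bed)
    if p.suffix == ".bed":
        p = p.with_suffix("")
    return p.with_suffix(".bed"), p.with_suffix(".bim"), p.with_suffix(".fam")


def read_plink(
    prefix, bim_path=None, fam_path=None
) -> tuple[GenotypeMatrix, pd.DataFrame, list[str]]:
    """Read a PLINK 1 binary trio.

    Accepts either a shared prefix (``data`` for data.bed/.bim/.fam) or three
    explicit paths. Returns the genotype matrix, the per-SNP metadata table
    (with QC fields filled in) and the sample IDs in .fam order.
    """
    if bim_path is None or fam_path is None:
        bed_path, bim_path, fam_path = _paths(prefix)
    else:
        bed_path = Path(prefix)
    for f in (bed_path, bim_path, fam_path):
        if not Path(f).exists():
            raise FileNotFoundError(f)

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    m, n = len(bim), len(fam)
    if m < 1 or n < 1:
        raise FormatError(f"empty panel: {m} SNPs, {n} samples")

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise FormatError(
            f"{bed_path}: bad magic bytes {raw[:3].tobytes()!r}; "
            "expected SNP-major PLINK 1 .bed"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + m * bytes_per_snp
    if raw.size != expected:
        raise FormatError(
            f"{bed_path}: size mismatch, got {raw.size} bytes, expected {expected} "
            f"for {m} SNPs x {n} samples"
        )
    codes = _DECODE[raw[3:].reshape(m, bytes_per_snp)].reshape(m, 4 * bytes_per_snp)
    codes = codes[:, :n]
    miss_rows, miss_cols = np.nonzero(codes == _MISSING_SENTINEL)
    values = np.where(codes == _MISSING_SENTINEL, 0, codes).astype(np.int8)
    geno = GenotypeMatrix(values, miss_rows, miss_cols)
    meta = snp_metadata(
        geno,
        chrom=bim["chrom"].to_numpy(),
        ids=bim["id"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        allele1=bim["allele1"].to_numpy(),
        allele2=bim["allele2"].to_numpy(),
    )
    return geno, meta, fam["iid"].tolist()


def write_plink(
    prefix,
    geno: GenotypeMatrix,
    meta: pd.DataFrame | None = None,
    sample_ids: list[str] | None = None,
) -> None:
    """Write a genotype matrix as a PLINK 1 binary trio (SNP-major)."""
    prefix = Path(prefix)
    os.makedirs(prefix.parent, exist_ok=True)
    m, n = geno.m, geno.n
    if meta is None:
        meta = snp_metadata(geno)
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]

    codes = geno.values.astype(np.uint8)
    if geno.n_missing:
        codes = codes.copy()
        codes[geno.missing_rows, geno.missing_cols] = _MISSING_SENTINEL
    bits = _ENCODE[codes]
    pad = (-n) % 4
    if pad:
        # trailing pad bits are zero-filled, as PLINK writes them
        bits = np.hstack([bits, np.zeros((m, pad), dtype=np.uint8)])
    bits = bits.reshape(m, -1, 4)
    packed = (
        bits[:, :, 0]
        | (bits[:, :, 1] << 2)
        | (bits[:, :, 2] << 4)
        | (bits[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        packed.tofile(fh)

    bim = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "id": meta["id"],
            "cm": 0,
            "pos": meta["pos"],
            "allele1": meta["allele1"],
            "allele2": meta["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": sample_ids,
            "iid": sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
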
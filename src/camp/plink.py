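"""PLINK 1 binary genotype I/O (BED/BIM/FAM, SNP-major).

The .bed payload packs four genotypes per byte, least-significant pair
first; per the PLINK 1 convention the two-bit codes are

    00 = homozygous A1   (2 copies of the counted allele)
    01 = missing
    10 = heterozygous    (1 copy)
    11 = homozygous A2   (0 copies)

Dosages returned here count the BIM A1 allele; missing genotypes are NaN.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import BadMagic, DimensionMismatch, TruncatedFile

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code -> dosage of the A1 allele
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
# dosage (0,1,2, missing=3) -> two-bit code
_DOSAGE_TO_CODE = np.array([3, 2, 0, 1], dtype=np.uint8)

BIM_COLUMNS = ["chromosome", "marker_id", "cm", "position", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_bim(path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chromosome": str, "marker_id": str, "a1": str, "a2": str})
    return bim


def read_fam(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS,
                       dtype={"fid": str, "iid": str})


def read_plink_bed(prefix) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Read ``prefix``.bed/.bim/.fam.

    Returns (raw dosage matrix counting the A1 allele with NaN for missing,
    BIM table, sample ids).
    """
    prefix = str(prefix)
    bim = read_bim(prefix + ".bim")
    fam = read_fam(prefix + ".fam")
    n, m = len(fam), len(bim)

    payload = Path(prefix + ".bed").read_bytes()
    if payload[:3] != _MAGIC:
        raise BadMagic(
            f"{prefix}.bed does not start with the SNP-major PLINK1 magic bytes"
        )
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(payload) < expected:
        raise TruncatedFile(
            f"{prefix}.bed holds {len(payload)} bytes; {expected} required "
            f"for {n} samples x {m} markers"
        )
    if len(payload) > expected:
        raise DimensionMismatch(
            f"{prefix}.bed holds {len(payload) - expected} unexplained trailing bytes"
        )

    raw = np.frombuffer(payload, dtype=np.uint8, offset=3)
    raw = raw.reshape(m, bytes_per_marker)
    # unpack the four 2-bit codes of every byte, LSB pair first
    codes = np.stack([(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, bytes_per_marker * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()   # (n, m)
    return dosages, bim, fam["iid"].to_numpy()


def write_plink_bed(prefix, dosages, bim: pd.DataFrame, sample_ids) -> None:
    """Write raw A1-allele dosages (0/1/2, NaN = missing) as BED/BIM/FAM."""
    prefix = str(prefix)
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if len(bim) != m or len(sample_ids) != n:
        raise DimensionMismatch("dosage shape does not match bim/fam lengths")

    lev = np.where(np.isnan(dosages), 3, dosages).astype(np.intp)
    codes = _DOSAGE_TO_CODE[lev].T                      # (m, n)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.ones((m, pad), dtype=np.uint8)], axis=1
        )  # pad with "missing"
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    Path(prefix + ".bed").write_bytes(_MAGIC + packed.tobytes())

    bim[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": sample_ids, "iid": sample_ids,
        "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
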
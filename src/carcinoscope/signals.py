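"""Binned read-count / BAF containers and the purity–ploidy lattice.

The lattice maps an absolute allele-specific state to observable space for a
tumor of purity ``p`` diluted by normal (diploid, heterozygous) cells:

* relative read count of total copy number ``c`` against mean ploidy ``psi``:
  ``RC(c) = (p*c + 2*(1-p)) / (p*psi + 2*(1-p))``
* B-allele fraction of genotype ``(a, b)`` (a = major, b = minor):
  ``BAF(a, b) = (p*b + (1-p)) / (p*(a+b) + 2*(1-p))``

BAF is always folded to the major-allele side (>= 0.5) since phasing is not
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "raw_rc", "gc"]
HET_COLUMNS = ["chrom", "pos", "baf", "depth"]


@dataclass
class BinnedSignal:
    """Per-bin read counts with GC content, plus heterozygous-site BAFs."""

    bins: pd.DataFrame  # chrom, start, end, raw_rc, gc [, corrected_rc]
    hets: pd.DataFrame  # chrom, pos, baf, depth

    def __post_init__(self) -> None:
        for col in BIN_COLUMNS:
            if col not in self.bins.columns:
                raise ValueError(f"bins missing column {col!r}")
        for col in HET_COLUMNS:
            if col not in self.hets.columns:
                raise ValueError(f"hets missing column {col!r}")
        b = self.bins
        if ((b["gc"] < 0) | (b["gc"] > 1)).any():
            raise ValueError("gc outside [0, 1]")
        for _, grp in b.groupby("chrom", sort=False):
            s = grp.sort_values("start")
            if (s["start"].values[1:] <= s["end"].values[:-1]).any():
                raise ValueError("overlapping bins")

    @property
    def bin_size(self) -> int:
        return int((self.bins["end"] - self.bins["start"] + 1).mode().iloc[0])


def expected_rc(total_cn, purity: float, mean_ploidy: float):
    """Relative (mean-1-normalized) read count of a total copy number."""
    c = np.asarray(total_cn, dtype=float)
    return (purity * c + 2.0 * (1.0 - purity)) / (
        purity * mean_ploidy + 2.0 * (1.0 - purity))


def expected_baf(major_cn, minor_cn, purity: float, folded: bool = True):
    """BAF of genotype (major, minor); folded reports the major-allele side."""
    a = np.asarray(major_cn, dtype=float)
    b = np.asarray(minor_cn, dtype=float)
    tot = purity * (a + b) + 2.0 * (1.0 - purity)
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(tot > 0, (purity * b + (1.0 - purity)) / tot, 0.5)
    return np.where(baf < 0.5, 1.0 - baf, baf) if folded else baf


def fold(baf):
    baf = np.asarray(baf, dtype=float)
    return np.where(baf < 0.5, 1.0 - baf, baf)


def genotype_states(max_cn: int) -> list[tuple[int, int]]:
    """All (major, minor) with major >= minor >= 0 and major+minor <= max_cn."""
    return [(a, b) for tot in range(max_cn + 1)
            for b in range(tot // 2 + 1)
            for a in [tot - b] if a >= b]
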
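"""Allele-specific copy-number segment containers.

A segment profile tiles the covered genome with ``(major_cn, minor_cn)``
segments (1-based inclusive coordinates) and carries the tumor purity and the
genome model whose arm boundaries downstream scar statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "major_cn", "minor_cn"]


def _as_segment_frame(segments) -> pd.DataFrame:
    df = pd.DataFrame(segments, columns=None if isinstance(segments, pd.DataFrame) else SEGMENT_COLUMNS)
    df = df[SEGMENT_COLUMNS].copy()
    for col in SEGMENT_COLUMNS[1:]:
        df[col] = df[col].astype(int)
    if (df["minor_cn"] > df["major_cn"]).any():
        raise ValueError("minor_cn exceeds major_cn")
    if (df["minor_cn"] < 0).any():
        raise ValueError("negative copy number")
    if (df["total_cn"] != df["major_cn"] + df["minor_cn"]).any():
        raise ValueError("total_cn must equal major_cn + minor_cn")
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for _, grp in df.groupby("chrom", sort=False):
        if (grp["start"].values[1:] <= grp["end"].values[:-1]).any():
            raise ValueError("overlapping segments")
    return df


@dataclass
class SegmentProfile:
    """Ordered allele-specific segments plus purity and genome model."""

    segments: pd.DataFrame
    purity: float
    genome: GenomeModel
    genotype_known: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        self.segments = _as_segment_frame(self.segments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"] + 1).to_numpy()

    @property
    def modal_ploidy(self) -> int:
        """Length-weighted mode of the total copy number."""
        w = pd.Series(self.lengths).groupby(self.segments["total_cn"]).sum()
        return int(w.idxmax())

    @property
    def mean_ploidy(self) -> float:
        """Length-weighted mean total copy number."""
        l = self.lengths
        return float((self.segments["total_cn"].to_numpy() * l).sum() / l.sum())

    def with_segments(self, segments) -> "SegmentProfile":
        return SegmentProfile(segments, self.purity, self.genome,
                              self.genotype_known, dict(self.meta))

    def arm_segments(self):
        """Yield (arm, segment sub-frame clipped to the arm)."""
        for arm in self.genome.arms():
            sel = self.segments[(self.segments["chrom"] == arm.chrom)
                                & (self.segments["end"] >= arm.start)
                                & (self.segments["start"] <= arm.end)]
            if sel.empty:
                continue
            sel = sel.copy()
            sel["start"] = sel["start"].clip(lower=arm.start)
            sel["end"] = sel["end"].clip(upper=arm.end)
            yield arm, sel.reset_index(drop=True)


def merge_adjacent(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge touching same-chromosome runs with identical (major, minor)."""
    df = _as_segment_frame(segments)
    rows: list[list] = []
    for _, seg in df.iterrows():
        if (rows and rows[-1][0] == seg["chrom"]
                and rows[-1][2] + 1 == seg["start"]
                and rows[-1][4] == seg["major_cn"]
                and rows[-1][5] == seg["minor_cn"]):
            rows[-1][2] = seg["end"]
        else:
            rows.append(list(seg[SEGMENT_COLUMNS]))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def profile_from_arm_states(genome: GenomeModel, arm_states: dict,
                            purity: float = 1.0) -> SegmentProfile:
    """Build a profile from ``{(chrom, arm): [(length, major, minor), ...]}``.

    Each arm's listed blocks must sum to the arm length; a single
    ``(major, minor)`` tuple means one uniform segment covering the arm.
    """
    rows = []
    for arm in genome.arms():
        spec = arm_states.get((arm.chrom, arm.name))
        if spec is None:
            continue
        if isinstance(spec, tuple):
            spec = [(arm.length, spec[0], spec[1])]
        pos = arm.start
        for length, major, minor in spec:
            rows.append((arm.chrom, pos, pos + int(length) - 1,
                         major + minor, major, minor))
            pos += int(length)
        if pos - 1 != arm.end:
            raise ValueError(f"blocks do not tile arm {arm.chrom}{arm.name}")
    return SegmentProfile(pd.DataFrame(rows, columns=SEGMENT_COLUMNS),
                          purity, genome)
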
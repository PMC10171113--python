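"""Genome models: chromosome lengths and arm boundaries.

All coordinates in this package are 1-based inclusive. The default model is a
miniature genome (four 100-Mb chromosomes with the centromere at 50 Mb) so that
whole-pipeline tests run in seconds; a packaged hg19 arm table is available for
real-scale coordinates. Nothing in the copy-number or scar arithmetic depends on
chromosome count or size, only on arm boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import pandas as pd


@dataclass(frozen=True)
class Arm:
    chrom: str
    name: str  # "p" or "q"
    start: int  # 1-based inclusive
    end: int  # inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths plus centromere positions.

    The centromere position splits each chromosome into a p arm
    ``[1, centromere]`` and a q arm ``[centromere+1, length]``. Acrocentric
    chromosomes may have a centromere of 0, giving a single q arm.
    """

    chrom_lengths: tuple[tuple[str, int], ...]
    centromeres: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        cen = dict(self.centromeres)
        for chrom, length in self.chrom_lengths:
            c = cen.get(chrom, 0)
            if not 0 <= c <= length:
                raise ValueError(f"centromere of {chrom} outside chromosome")

    @property
    def chroms(self) -> list[str]:
        return [c for c, _ in self.chrom_lengths]

    def length(self, chrom: str) -> int:
        return dict(self.chrom_lengths)[chrom]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chrom_lengths)

    def centromere(self, chrom: str) -> int:
        return dict(self.centromeres).get(chrom, 0)

    def arms(self) -> Iterator[Arm]:
        for chrom, length in self.chrom_lengths:
            cen = self.centromere(chrom)
            if cen > 0:
                yield Arm(chrom, "p", 1, cen)
            if cen < length:
                yield Arm(chrom, "q", cen + 1, length)

    def arm_of(self, chrom: str, pos: int) -> Arm:
        for arm in self.arms():
            if arm.chrom == chrom and arm.start <= pos <= arm.end:
                return arm
        raise KeyError(f"{chrom}:{pos} outside genome model")

    def arm_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.chrom, a.name, a.start, a.end) for a in self.arms()],
            columns=["chrom", "arm", "start", "end"],
        )


def miniature_genome(n_chroms: int = 4, chrom_length: int = 100_000_000,
                     centromere: int = 50_000_000) -> GenomeModel:
    """Desk-scale genome: ``n_chroms`` equal metacentric chromosomes."""
    return GenomeModel(
        chrom_lengths=tuple((f"chr{i + 1}", chrom_length) for i in range(n_chroms)),
        centromeres=tuple((f"chr{i + 1}", centromere) for i in range(n_chroms)),
    )


def hg19_genome() -> GenomeModel:
    """GRCh37 autosomes + X, arm boundaries from the packaged table."""
    with resources.files("carcinoscope.data").joinpath("hg19_arms.tsv").open() as fh:
        tab = pd.read_csv(fh, sep="\t")
    return GenomeModel(
        chrom_lengths=tuple(zip(tab["chrom"], tab["length"].astype(int))),
        centromeres=tuple(zip(tab["chrom"], tab["centromere"].astype(int))),
    )
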
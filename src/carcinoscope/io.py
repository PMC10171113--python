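"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are TSV; coordinates are 1-based inclusive (the SEG writer keeps
that convention and says so in its header comment). BEDPE columns follow the
usual chrom1/pos1/strand1/chrom2/pos2/strand2 layout plus class/support/span.
"""

from __future__ import annotations

import pandas as pd

from .genome import GenomeModel
from .segments import SEGMENT_COLUMNS, SegmentProfile
from .signals import BinnedSignal

SV_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
              "sv_class", "supporting_reads", "span"]


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mutations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_seg(profile: SegmentProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# purity={profile.purity:.4f} "
                 f"modal_ploidy={profile.modal_ploidy} "
                 f"coordinates=1-based-inclusive\n")
        profile.segments[SEGMENT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_seg(path, genome: GenomeModel, purity: float | None = None
             ) -> SegmentProfile:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            segs = pd.read_csv(fh, sep="\t")
        else:
            segs = pd.read_csv(path, sep="\t")
    p = purity if purity is not None else float(meta.get("purity", 1.0))
    return SegmentProfile(segs, p, genome)


def write_bedpe(svs: pd.DataFrame, path) -> None:
    svs[SV_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bedpe(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_binned_signal(signal: BinnedSignal, bins_path, hets_path) -> None:
    signal.bins.to_csv(bins_path, sep="\t", index=False)
    signal.hets.to_csv(hets_path, sep="\t", index=False)


def read_binned_signal(bins_path, hets_path) -> BinnedSignal:
    return BinnedSignal(pd.read_csv(bins_path, sep="\t"),
                        pd.read_csv(hets_path, sep="\t"))


def write_msi_tables(tumor: pd.DataFrame, normal: pd.DataFrame, path_prefix) -> None:
    tumor.rename_axis("site").to_csv(f"{path_prefix}.tumor.tsv", sep="\t")
    normal.rename_axis("site").to_csv(f"{path_prefix}.normal.tsv", sep="\t")


def read_msi_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.rename_axis(index_label).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def clone_tree_newick(nodes) -> str:
    """Newick-like serialization of a clone tree (ids only)."""
    children: dict = {}
    root = None
    for node in nodes:
        if node.parent is None:
            root = node.clone_id
        else:
            children.setdefault(node.parent, []).append(node.clone_id)

    def render(cid: str) -> str:
        kids = children.get(cid, [])
        if not kids:
            return cid
        return "(" + ",".join(render(c) for c in kids) + ")" + cid

    return (render(root) + ";") if root else ";"
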
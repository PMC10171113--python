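"""Genomic-scar phenotyping.

Five scar readouts summarize a tumor genome: large-scale state transitions
(LST; copy-number breaks between >= 10 Mb flanks after 3 Mb smoothing, counted
per arm), the tandem-duplicator-phenotype score (Menghi-style dispersion of
intra-chromosomal duplications against chromosome length), the microsatellite
instability fraction (per-site chi-squared comparison of tumor vs normal
repeat-length distributions), APOBEC kataegis clusters (four joint criteria),
and the derived homologous-recombination-deficiency status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, gaussian_kde

from .channels import is_tpc_cd
from .segments import SegmentProfile, merge_adjacent

MB = 1_000_000

# ---------------------------------------------------------------------------
# smoothing and LST


def smooth_profile(profile: SegmentProfile, min_size: int = 3 * MB) -> SegmentProfile:
    """Remove copy-number variations shorter than ``min_size`` (strict).

    Sub-threshold excursions are iteratively absorbed: if the two neighbors
    share a state the three segments merge; otherwise the short segment joins
    its longer neighbor. Runs to a fixpoint, so smoothing is idempotent.
    """
    chroms = []
    for chrom, grp in profile.segments.groupby("chrom", sort=False):
        segs = grp.sort_values("start").to_dict("records")
        changed = True
        while changed:
            changed = False
            lengths = [s["end"] - s["start"] + 1 for s in segs]
            short = [i for i, ln in enumerate(lengths)
                     if ln < min_size and len(segs) > 1]
            if not short:
                break
            i = min(short, key=lambda j: lengths[j])
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i < len(segs) - 1 else None
            if left is not None and right is not None and (
                    left["major_cn"], left["minor_cn"]) == (
                    right["major_cn"], right["minor_cn"]):
                left["end"] = right["end"]
                del segs[i:i + 2]
            else:
                def _len(s):
                    return 0 if s is None else s["end"] - s["start"] + 1
                host = left if _len(left) >= _len(right) else right
                if host is left:
                    left["end"] = segs[i]["end"]
                else:
                    right["start"] = segs[i]["start"]
                del segs[i]
            changed = True
        chroms.append(pd.DataFrame(segs))
    merged = merge_adjacent(pd.concat(chroms, ignore_index=True))
    return profile.with_segments(merged)


def count_lst(profile: SegmentProfile, min_flank: int = 10 * MB) -> int:
    """Large-scale state transitions summed over chromosome arms.

    The profile is expected to be smoothed (3 Mb filter) already. Per arm,
    every change of total copy number between adjacent runs is counted iff
    both flanking runs span at least ``min_flank`` within the arm; breaks at
    the centromere never contribute (arms are scanned independently).
    """
    if not list(profile.genome.arms()):
        raise ValueError("genome model has no arm table")
    n = 0
    for _, segs in profile.arm_segments():
        runs: list[list] = []  # [total_cn, length]
        for _, s in segs.iterrows():
            ln = s["end"] - s["start"] + 1
            if runs and runs[-1][0] == s["total_cn"]:
                runs[-1][1] += ln
            else:
                runs.append([int(s["total_cn"]), int(ln)])
        for i in range(1, len(runs)):
            if runs[i - 1][1] >= min_flank and runs[i][1] >= min_flank:
                n += 1
    return n


def brcaness_surrogate(lst_count: int, threshold: int = 20) -> bool:
    """High LST count (strictly > 20) as a surrogate of BRCAness."""
    return lst_count > threshold


# ---------------------------------------------------------------------------
# tandem duplicator phenotype


def tdp_score(svs: pd.DataFrame, genome, c0: float = 0.71,
              span_window: tuple[float, float] = (1_000.0, 100_000.0)
              ) -> tuple[float, float, bool]:
    """Menghi-style tandem-duplicator-phenotype score.

    Only intra-chromosomal duplication-class records are used. The dispersion
    ``D = sum_chrom |obs - exp| / N`` (expected counts proportional to
    chromosome length) gives ``score = c0 - D``; a positive score plus a
    modal span (kernel-density peak of log10 span) inside ``span_window``
    flags the phenotype. Returns (score, span_mode, flag).
    """
    td = svs[(svs["sv_class"] == "duplication")
             & (svs["chrom1"] == svs["chrom2"])]
    if td.empty:
        return float("nan"), float("nan"), False
    n = len(td)
    lens = pd.Series(dict(genome.chrom_lengths), dtype=float)
    exp = n * lens / lens.sum()
    obs = td["chrom1"].value_counts().reindex(lens.index, fill_value=0)
    score = c0 - float((obs - exp).abs().sum() / n)

    spans = np.log10(td["span"].to_numpy(dtype=float).clip(min=1))
    if len(spans) > 1 and spans.std() > 1e-9:
        grid = np.linspace(2.0, 7.0, 501)
        span_mode = float(10 ** grid[np.argmax(gaussian_kde(spans)(grid))])
    else:
        span_mode = float(10 ** spans[0])
    flag = score > 0 and span_window[0] <= span_mode <= span_window[1]
    return score, span_mode, flag


# ---------------------------------------------------------------------------
# microsatellite instability


def msi_flag(fraction: float, threshold: float = 0.20) -> bool:
    """A tumor is MSI iff the unstable-site fraction strictly exceeds 20%."""
    return fraction > threshold


@dataclass
class MsiResult:
    fraction: float
    flag: bool | None       # None when no site was assessable
    n_assessed: int
    per_site: pd.DataFrame


def _pooled_chi2_p(t: np.ndarray, n: np.ndarray) -> float:
    """Homogeneity chi-squared with rare length bins pooled to expected >= 5."""
    table = np.vstack([t, n]).astype(float)
    table = table[:, table.sum(axis=0) > 0]
    while table.shape[1] > 2:
        exp = (table.sum(axis=1, keepdims=True)
               @ table.sum(axis=0, keepdims=True)) / table.sum()
        if exp.min() >= 5:
            break
        j = int(np.argmin(table.sum(axis=0)))
        nb = j - 1 if j > 0 else j + 1
        table[:, nb] += table[:, j]
        table = np.delete(table, j, axis=1)
    if table.shape[1] < 2:
        return 1.0
    return float(chi2_contingency(table, correction=False)[1])


def msi_score(tumor: pd.DataFrame, normal: pd.DataFrame,
              min_reads: int = 20, alpha: float = 0.05,
              threshold: float = 0.20) -> MsiResult:
    """Fraction of microsatellite sites with unstable length distributions.

    ``tumor`` and ``normal`` are sites x length-bin read-count tables with a
    shared index. Sites with fewer than ``min_reads`` reads in either sample
    are excluded; a site is unstable when the pooled Pearson chi-squared
    homogeneity test rejects at ``alpha``.
    """
    sites = tumor.index.intersection(normal.index)
    rows = []
    for site in sites:
        t = tumor.loc[site].to_numpy(dtype=float)
        n = normal.loc[site].to_numpy(dtype=float)
        if t.sum() < min_reads or n.sum() < min_reads:
            continue
        p = _pooled_chi2_p(t, n)
        rows.append((site, p, p < alpha))
    per_site = pd.DataFrame(rows, columns=["site", "p_value", "unstable"])
    if per_site.empty:
        return MsiResult(float("nan"), None, 0, per_site)
    frac = float(per_site["unstable"].mean())
    return MsiResult(frac, msi_flag(frac, threshold), len(per_site), per_site)


# ---------------------------------------------------------------------------
# kataegis


@dataclass
class KataegisEvent:
    chrom: str
    start: int
    end: int
    mutation_ids: list
    spectrum_fraction: float    # TpC C>D share of the cluster
    vaf_spread: float
    clone: object
    sv_distance: float          # bp to the nearest rearrangement breakpoint


def _sv_breakpoints(svs: pd.DataFrame) -> pd.DataFrame:
    bps = pd.concat([
        svs[["chrom1", "pos1"]].rename(columns={"chrom1": "chrom", "pos1": "pos"}),
        svs[["chrom2", "pos2"]].rename(columns={"chrom2": "chrom", "pos2": "pos"}),
    ], ignore_index=True)
    return bps.sort_values(["chrom", "pos"])


def detect_kataegis(mutations: pd.DataFrame, svs: pd.DataFrame | None,
                    n_min: int = 6, k: int = 5, d_max: float = 1_000.0,
                    spectrum_min: float = 0.8, vaf_tol: float = 0.15,
                    sv_window: int = 50_000) -> list[KataegisEvent]:
    """APOBEC kataegis: clusters passing all four joint criteria.

    (i) local hypermutation — runs of >= ``n_min`` mutations whose mean
    distance to their ``k`` nearest neighbors is <= ``d_max``; (ii) the
    cluster spectrum is dominated by C>A/C>G/C>T at TpC; (iii) the mutations
    share similar VAFs (spread <= ``vaf_tol``) or the same clone label; (iv)
    the cluster lies within ``sv_window`` of a rearrangement breakpoint.
    """
    if svs is None or len(svs) == 0:
        warnings.warn("no SV table: the rearrangement-proximity criterion is "
                      "unsatisfiable, rejecting all candidates", stacklevel=2)
        return []
    bps = _sv_breakpoints(svs)
    events: list[KataegisEvent] = []
    for chrom, grp in mutations.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=float)
        m = len(pos)
        if m < n_min:
            continue
        knn = np.empty(m)
        for i in range(m):
            lo, hi = max(0, i - k), min(m, i + k + 1)
            d = np.abs(pos[lo:hi] - pos[i])
            d = np.sort(d[d > 0])[:k]
            knn[i] = d.mean() if len(d) else np.inf
        flagged = knn <= d_max
        # maximal runs of flagged mutations
        i = 0
        while i < m:
            if not flagged[i]:
                i += 1
                continue
            j = i
            while j + 1 < m and flagged[j + 1]:
                j += 1
            if j - i + 1 >= n_min:
                sub = grp.iloc[i:j + 1]
                spec = float(sub["channel"].map(is_tpc_cd).mean())
                spread = float(sub["vaf"].max() - sub["vaf"].min())
                clones = sub["clone"].unique() if "clone" in sub.columns else []
                same_clone = len(clones) == 1
                cb = bps[bps["chrom"] == chrom]["pos"].to_numpy()
                if len(cb):
                    dist = float(np.min(np.minimum(
                        np.abs(cb - sub["pos"].iloc[0]),
                        np.abs(cb - sub["pos"].iloc[-1]))))
                    inside = ((cb >= sub["pos"].iloc[0])
                              & (cb <= sub["pos"].iloc[-1])).any()
                    if inside:
                        dist = 0.0
                else:
                    dist = np.inf
                if (spec >= spectrum_min
                        and (spread <= vaf_tol or same_clone)
                        and dist <= sv_window):
                    events.append(KataegisEvent(
                        str(chrom), int(sub["pos"].iloc[0]),
                        int(sub["pos"].iloc[-1]), list(sub["id"]),
                        spec, spread, clones[0] if same_clone else None, dist))
            i = j + 1
    return events


# ---------------------------------------------------------------------------
# HRD status

BRCA_STATES = ("altered", "wild-type", "promoter-hypermethylated")


def hrd_status(lst_count: int, brca_status: str,
               methylation_counts_as_altered: bool = True) -> str:
    """HRD classification from LST count and BRCA1/2 state.

    High: BRCA1/2 altered or LST > 16. Low: BRCA1/2 wild-type and LST < 6.
    Everything else is intermediary. Promoter hypermethylation counts as an
    alteration unless disabled.
    """
    if lst_count < 0:
        raise ValueError("lst_count must be >= 0")
    if brca_status not in BRCA_STATES:
        raise ValueError(f"brca_status must be one of {BRCA_STATES}")
    altered = brca_status == "altered" or (
        brca_status == "promoter-hypermethylated"
        and methylation_counts_as_altered)
    if altered or lst_count > 16:
        return "high"
    if not altered and lst_count < 6:
        return "low"
    return "intermediary"


# ---------------------------------------------------------------------------
# per-sample bundle


@dataclass
class SampleScars:
    lst_count: int
    tdp_score: float
    tdp_flag: bool
    msi_fraction: float
    msi_flag: bool | None
    kataegis_events: list = field(default_factory=list)
    brca_status: str = "wild-type"
    hrd_status: str = "intermediary"
    brcaness_surrogate: bool = False


def compute_sample_scars(profile: SegmentProfile, svs: pd.DataFrame,
                         mutations: pd.DataFrame,
                         msi_tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
                         brca_status: str = "wild-type",
                         **kataegis_params) -> SampleScars:
    """Run the full scar panel on one sample."""
    sm = smooth_profile(profile)
    lst = count_lst(sm)
    td, span_mode, td_flag = tdp_score(svs, profile.genome)
    if msi_tables is not None:
        msi = msi_score(*msi_tables)
        msi_frac, msi_fl = msi.fraction, msi.flag
    else:
        msi_frac, msi_fl = float("nan"), None
    events = detect_kataegis(mutations, svs, **kataegis_params) if len(svs) else []
    return SampleScars(
        lst_count=lst, tdp_score=td, tdp_flag=td_flag,
        msi_fraction=msi_frac, msi_flag=msi_fl, kataegis_events=events,
        brca_status=brca_status, hrd_status=hrd_status(lst, brca_status),
        brcaness_surrogate=brcaness_surrogate(lst))
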
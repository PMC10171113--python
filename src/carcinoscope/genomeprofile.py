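"""Allele-specific copy-number inference and SV utilities.

The caller follows a three-step design: (1) GC-bias correction of binned read
counts with two nested smoothing windows, (2) grid estimation of tumor purity
and mean ploidy from the joint (read count, BAF) cluster lattice, and (3)
simultaneous segmentation of both signals with a bivariate hidden Markov model
whose states are all allele-specific genotypes (major, minor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .segments import SEGMENT_COLUMNS, SegmentProfile, merge_adjacent
from .genome import GenomeModel, miniature_genome
from .signals import (BinnedSignal, expected_baf, expected_rc, fold,
                      genotype_states)

# ---------------------------------------------------------------------------
# step 1: GC correction


def _lowess_factor(y: np.ndarray, x: np.ndarray, frac: float) -> np.ndarray:
    fit = lowess(y, x, frac=frac, return_sorted=True)
    f = np.interp(x, fit[:, 0], fit[:, 1])
    return np.clip(f, 1e-6 * np.nanmean(y) + 1e-12, None)


def gc_correct(bins: pd.DataFrame, long_window_bins: int = 5,
               frac: float = 0.3, use_long_window: bool = True) -> pd.DataFrame:
    """Remove GC bias from raw read counts with two nested windows.

    The short-scale component smooths read count against per-bin GC; the
    long-scale component against GC averaged over ``long_window_bins``
    neighboring bins (additively nested: fitted on the residual ratio).
    Returns a copy of ``bins`` with a ``corrected_rc`` column normalized to
    mean 1.
    """
    if len(bins) < 200:
        raise ValueError("need at least 200 bins to fit the GC model")
    out = bins.copy()
    rc = out["raw_rc"].to_numpy(dtype=float)
    gc = out["gc"].to_numpy(dtype=float)
    if np.ptp(gc) < 1e-9:
        warnings.warn("constant GC content: identity correction applied",
                      stacklevel=2)
        out["corrected_rc"] = rc / rc.mean()
        return out
    if not use_long_window:
        ratio = rc / _lowess_factor(rc, gc, frac)
        out["corrected_rc"] = ratio / ratio.mean()
        return out
    gc_long = (out.groupby("chrom", sort=False)["gc"]
               .transform(lambda s: s.rolling(long_window_bins, center=True,
                                              min_periods=1).mean())
               .to_numpy())
    # backfit the two additive components: the window GC tracks are
    # correlated, so a single sequential pass leaves cross-talk behind. The
    # long-window term is kept linear — a flexible smoother at that scale can
    # absorb genuine copy-number structure, attenuating the CN contrast.
    f_short = np.ones_like(rc)
    f_long = np.ones_like(rc)
    for _ in range(3):
        f_short = _lowess_factor(rc / f_long, gc, frac)
        if np.ptp(gc_long) > 1e-9:
            resid = rc / f_short
            slope, intercept = np.polyfit(gc_long, resid, 1)
            f_long = np.clip(intercept + slope * gc_long,
                             1e-6 * np.nanmean(resid) + 1e-12, None)
    ratio = rc / (f_short * f_long)
    out["corrected_rc"] = ratio / ratio.mean()
    return out


# ---------------------------------------------------------------------------
# step 2: purity / mean-ploidy grid


@dataclass
class PloidyPurityFit:
    purity: float | None
    mean_ploidy: float | None
    score: float
    status: str  # "ok" or "unidentifiable"
    candidates: pd.DataFrame


def _folded_baf_estimate(baf: np.ndarray, depth: np.ndarray) -> float:
    """Noise-corrected major-allele fraction from unphased het BAFs.

    Folding |baf - 0.5| upward biases balanced regions, so the estimator
    subtracts the binomial sampling variance:
    ``fa = 0.5 + sqrt(max(0, mean((baf-0.5)^2) - mean(baf(1-baf)/depth)))``.
    """
    dev2 = float(np.mean((baf - 0.5) ** 2))
    noise = float(np.mean(baf * (1.0 - baf) / np.maximum(depth, 1)))
    return 0.5 + np.sqrt(max(0.0, dev2 - noise))


def _bin_baf(signal: BinnedSignal) -> pd.DataFrame:
    """Per-bin folded-BAF estimate (NaN where a bin covers no het site)."""
    bins = signal.bins.reset_index(drop=True).copy()
    bins["baf"] = np.nan
    bins["n_het"] = 0
    for chrom, grp in signal.hets.groupby("chrom", sort=False):
        sel = bins.index[bins["chrom"] == chrom]
        if len(sel) == 0:
            continue
        starts = bins.loc[sel, "start"].to_numpy()
        idx = np.searchsorted(starts, grp["pos"].to_numpy(), side="right") - 1
        ok = idx >= 0
        sub = pd.DataFrame({"bin": sel[idx[ok]],
                            "baf": grp["baf"].to_numpy()[ok],
                            "depth": grp["depth"].to_numpy()[ok]})
        for b, rows in sub.groupby("bin"):
            bins.loc[b, "baf"] = _folded_baf_estimate(
                rows["baf"].to_numpy(), rows["depth"].to_numpy())
            bins.loc[b, "n_het"] = len(rows)
    return bins


class PloidyPurityGrid(BaseEstimator):
    """Grid search for tumor purity and mean ploidy on the CN lattice.

    Bins are summarized into weighted (read-count, folded-BAF) cluster
    centers; each (purity, ploidy) candidate is scored by inverting the
    centers to implied (total, major) copy numbers and measuring their squared
    distance to the nearest valid integer state. Working in copy-number space
    (rather than signal space) makes the score diverge as purity goes to zero,
    which removes the classic low-purity degeneracy. Ties within ``tie_tol``
    (relative) prefer the lower ploidy, then the higher purity — a
    conservative resolution of the genome-doubling alias.
    """

    def __init__(self, purity_grid=None, ploidy_grid=None, max_cn: int = 8,
                 baf_weight: float = 1.0, tie_tol: float = 0.01,
                 n_runner_up: int = 5, block_bins: int = 100):
        self.purity_grid = purity_grid
        self.ploidy_grid = ploidy_grid
        self.max_cn = max_cn
        self.baf_weight = baf_weight
        self.tie_tol = tie_tol
        self.n_runner_up = n_runner_up
        self.block_bins = block_bins

    def fit(self, signal: BinnedSignal):
        if len(signal.hets) < 100:
            raise ValueError("need at least 100 heterozygous sites")
        if "corrected_rc" not in signal.bins.columns:
            raise ValueError("run gc_correct first (no corrected_rc column)")
        purities = (np.round(np.arange(0.05, 1.0001, 0.01), 4)
                    if self.purity_grid is None else np.asarray(self.purity_grid))
        ploidies = (np.round(np.arange(1.5, 6.0001, 0.05), 4)
                    if self.ploidy_grid is None else np.asarray(self.ploidy_grid))

        # summarize homogeneous bin runs into low-noise (rc, baf) centers:
        # block boundaries follow detected read-count jumps (rolling-median
        # shifts) so that centers do not straddle copy-number breakpoints,
        # and the folded-BAF estimate pools every het site in the block
        c_rc_l, c_baf_l, c_w_l = [], [], []
        bins_df = signal.bins.reset_index(drop=True)
        for chrom, grp in bins_df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            hets = signal.hets[signal.hets["chrom"] == chrom]
            starts = grp["start"].to_numpy()
            het_bin = np.searchsorted(starts, hets["pos"].to_numpy(),
                                      side="right") - 1
            rc_all = grp["corrected_rc"].to_numpy()
            med = pd.Series(rc_all).rolling(9, center=True,
                                            min_periods=1).median().to_numpy()
            jump = np.abs(np.diff(med))
            # noise-adaptive cut threshold: genuine breakpoints stand far
            # outside the rolling-median jitter
            sigma_j = 1.4826 * np.median(np.abs(jump - np.median(jump)))
            thr = np.median(jump) + 8.0 * max(sigma_j, 1e-4)
            cuts = np.flatnonzero(jump > thr) + 1
            edges = [0]
            for c in cuts:
                if c - edges[-1] >= 20:
                    edges.append(int(c))
            edges.append(len(grp))
            for lo, hi in zip(edges[:-1], edges[1:]):
                for sub_lo in range(lo, hi, self.block_bins):
                    sub_hi = min(sub_lo + self.block_bins, hi)
                    if sub_hi - sub_lo < 20 and sub_lo != lo:
                        sub_lo = max(lo, sub_hi - 20)
                    rc_vals = rc_all[sub_lo:sub_hi]
                    c_rc_l.append(float(np.median(rc_vals)))
                    m = (het_bin >= sub_lo) & (het_bin < sub_hi)
                    if m.sum() >= 5:
                        c_baf_l.append(_folded_baf_estimate(
                            hets["baf"].to_numpy()[m],
                            hets["depth"].to_numpy()[m]))
                    else:
                        c_baf_l.append(np.nan)
                    spread = np.median(np.abs(rc_vals - np.median(rc_vals)))
                    c_w_l.append((sub_hi - sub_lo)
                                 / (1.0 + (spread / 0.02) ** 2))
        c_rc = np.array(c_rc_l)
        c_baf = np.array(c_baf_l)
        c_w = np.array(c_w_l)
        has_baf = ~np.isnan(c_baf)
        c_baf = np.where(has_baf, c_baf, 0.5)

        wsum = c_w.sum()
        mean_rc = (c_rc * c_w).sum() / wsum
        sd_rc = np.sqrt(((c_rc - mean_rc) ** 2 * c_w).sum() / wsum)
        flat_baf = not has_baf.any() or np.all(
            np.abs(c_baf[has_baf] - 0.5) < 0.02)
        if sd_rc < 0.02 and flat_baf:
            self.fit_ = PloidyPurityFit(None, None, np.inf, "unidentifiable",
                                        pd.DataFrame())
            self.purity_, self.ploidy_ = None, None
            return self

        pp, qq = np.meshgrid(purities, ploidies, indexing="ij")
        pflat, qflat = pp.ravel(), qq.ravel()
        p = pflat[:, None]
        denom = pflat * qflat + 2.0 * (1.0 - pflat)
        # implied total CN of each cell under each (purity, ploidy)
        c_impl = (c_rc[None, :] * denom[:, None] - 2.0 * (1.0 - p)) / p
        c_int = np.clip(np.round(c_impl), 0, self.max_cn)
        d = (c_impl - c_int) ** 2
        # implied major-allele CN from folded BAF, against the valid range
        a_impl = (c_baf[None, :] * (p * c_int + 2.0 * (1.0 - p))
                  - (1.0 - p)) / p
        a_int = np.clip(np.round(a_impl), np.ceil(c_int / 2.0), c_int)
        d = d + np.where(has_baf[None, :],
                         self.baf_weight * (a_impl - a_int) ** 2, 0.0)
        scores = (d * c_w[None, :]).sum(axis=1) / wsum

        order = np.argsort(scores, kind="stable")
        s_best = scores[order[0]]
        tol = self.tie_tol * (s_best + 1e-12)
        tied = order[scores[order] <= s_best + tol]
        # among near-equal scores: lower ploidy, then higher purity
        pick = tied[np.lexsort((-pflat[tied], qflat[tied]))[0]]
        cand = pd.DataFrame({"purity": pflat[order[:self.n_runner_up]],
                             "mean_ploidy": qflat[order[:self.n_runner_up]],
                             "score": scores[order[:self.n_runner_up]]})
        self.fit_ = PloidyPurityFit(float(pflat[pick]), float(qflat[pick]),
                                    float(scores[pick]), "ok", cand)
        self.purity_ = self.fit_.purity
        self.ploidy_ = self.fit_.mean_ploidy
        return self


def estimate_ploidy_purity(signal: BinnedSignal, **params) -> PloidyPurityFit:
    """Functional wrapper over :class:`PloidyPurityGrid`."""
    return PloidyPurityGrid(**params).fit(signal).fit_


# ---------------------------------------------------------------------------
# step 3: bivariate HMM segmentation


def _mad_sigma(x: np.ndarray, floor: float = 1e-3) -> float:
    x = x[np.isfinite(x)]
    if len(x) < 3:
        return floor
    d = np.diff(x)
    return max(floor, 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


class BivariateSegmenter(BaseEstimator):
    """HMM over allele-specific states decoding (read count, folded BAF).

    States are all genotypes (major, minor) with total <= ``max_cn``; emissions
    are Gaussian around the purity/ploidy lattice means (per-bin mean folded
    BAF uses an sd shrunk by the het-site count); transitions keep the current
    state with probability 1 - ``switch_prob`` per bin. The most probable state
    path (Viterbi) is merged into segments.
    """

    def __init__(self, purity: float = 1.0, mean_ploidy: float = 2.0,
                 max_cn: int = 8, switch_prob: float = 1e-5,
                 sd_rc: float | None = None, sd_baf: float | None = None):
        self.purity = purity
        self.mean_ploidy = mean_ploidy
        self.max_cn = max_cn
        self.switch_prob = switch_prob
        self.sd_rc = sd_rc
        self.sd_baf = sd_baf

    def fit(self, signal: BinnedSignal):
        bins = _bin_baf(signal)
        if "corrected_rc" not in bins.columns:
            raise ValueError("run gc_correct first (no corrected_rc column)")
        self.states_ = genotype_states(self.max_cn)
        self.sd_rc_ = self.sd_rc or _mad_sigma(bins["corrected_rc"].to_numpy())
        self.sd_baf_ = self.sd_baf or _mad_sigma(bins["baf"].to_numpy())
        self._bins = bins
        return self

    def _emission_loglik(self, bins: pd.DataFrame) -> np.ndarray:
        rc = bins["corrected_rc"].to_numpy()
        baf = bins["baf"].to_numpy()
        n_het = bins["n_het"].to_numpy().clip(min=1)
        ll = np.empty((len(bins), len(self.states_)))
        for s, (a, b) in enumerate(self.states_):
            r = expected_rc(a + b, self.purity, self.mean_ploidy)
            ll[:, s] = -0.5 * ((rc - r) / self.sd_rc_) ** 2
            bf = expected_baf(a, b, self.purity)
            sd = self.sd_baf_ / np.sqrt(n_het)
            with np.errstate(invalid="ignore"):
                baf_term = -0.5 * ((baf - bf) / sd) ** 2
            ll[:, s] += np.where(np.isnan(baf), 0.0, baf_term)
        return ll

    def _viterbi(self, ll: np.ndarray) -> np.ndarray:
        n, k = ll.shape
        stay = np.log1p(-self.switch_prob)
        move = np.log(self.switch_prob / max(k - 1, 1))
        delta = ll[0].copy()
        back = np.zeros((n, k), dtype=np.int32)
        idx = np.arange(k)
        for t in range(1, n):
            # best predecessor is either the same state (stay) or the best
            # *other* state (move) — the transition matrix is uniform off-diagonal
            order = np.argsort(delta)
            best_j, second_j = int(order[-1]), int(order[-2]) if k > 1 else 0
            other_val = np.where(idx == best_j, delta[second_j], delta[best_j])
            other_idx = np.where(idx == best_j, second_j, best_j)
            stay_score = delta + stay
            move_score = other_val + move
            take_stay = stay_score >= move_score
            back[t] = np.where(take_stay, idx, other_idx)
            delta = np.where(take_stay, stay_score, move_score) + ll[t]
        path = np.empty(n, dtype=np.int32)
        path[-1] = int(np.argmax(delta))
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return path

    def predict(self, signal: BinnedSignal | None = None,
                genome: GenomeModel | None = None) -> SegmentProfile:
        bins = self._bins if signal is None else _bin_baf(signal)
        genome = genome or miniature_genome()
        rows = []
        no_baf_chroms = []
        for chrom, grp in bins.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            if grp["n_het"].sum() == 0:
                no_baf_chroms.append(chrom)
            ll = self._emission_loglik(grp)
            path = self._viterbi(ll)
            change = np.flatnonzero(np.diff(path)) + 1
            bounds = np.concatenate([[0], change, [len(grp)]])
            for i in range(len(bounds) - 1):
                a, b = self.states_[path[bounds[i]]]
                rows.append((chrom, int(grp["start"].iloc[bounds[i]]),
                             int(grp["end"].iloc[bounds[i + 1] - 1]),
                             a + b, a, b))
        segs = merge_adjacent(pd.DataFrame(rows, columns=SEGMENT_COLUMNS))
        prof = SegmentProfile(segs, self.purity, genome,
                              genotype_known=len(no_baf_chroms) == 0)
        if no_baf_chroms:
            prof.meta["genotype_unknown_chroms"] = no_baf_chroms
        return prof


def segment_bivariate(signal: BinnedSignal, purity: float, mean_ploidy: float,
                      max_cn: int = 8, genome: GenomeModel | None = None,
                      **params) -> SegmentProfile:
    """Functional wrapper over :class:`BivariateSegmenter`."""
    seg = BivariateSegmenter(purity=purity, mean_ploidy=mean_ploidy,
                             max_cn=max_cn, **params)
    return seg.fit(signal).predict(genome=genome)


# ---------------------------------------------------------------------------
# genome-wide CNA summaries


def compute_fga(profile: SegmentProfile) -> float:
    """Fraction of the genome with total CN different from the modal ploidy."""
    if profile.segments.empty:
        raise ValueError("empty profile")
    lengths = profile.lengths
    altered = profile.segments["total_cn"].to_numpy() != profile.modal_ploidy
    return float(lengths[altered].sum() / lengths.sum())


def count_breakpoints(profile: SegmentProfile, on: str = "genotype") -> int:
    """CNA breakpoints: state changes between adjacent same-chromosome segments.

    ``on='genotype'`` counts (major, minor) changes; ``on='total'`` only total
    CN changes. Chromosome ends contribute no breakpoints.
    """
    if on not in ("genotype", "total"):
        raise ValueError("on must be 'genotype' or 'total'")
    n = 0
    for _, grp in profile.segments.groupby("chrom", sort=False):
        if on == "genotype":
            state = list(zip(grp["major_cn"], grp["minor_cn"]))
        else:
            state = list(grp["total_cn"])
        n += sum(1 for i in range(1, len(state)) if state[i] != state[i - 1])
    return n


# ---------------------------------------------------------------------------
# structural variants

SV_CLASSES = ("deletion", "duplication", "inversion", "translocation")


def classify_sv(bp1: tuple, bp2: tuple) -> str:
    """Classify an SV from its two oriented breakpoints.

    Breakpoints are (chrom, pos, orientation) with orientation in {+, -}.
    Different chromosomes give a translocation; on the same chromosome the
    convention is (+,-) deletion-type, (-,+) duplication-type, and equal
    orientations inversion-type.
    """
    (c1, p1, o1), (c2, p2, o2) = bp1, bp2
    for o in (o1, o2):
        if o not in ("+", "-"):
            raise ValueError(f"missing or invalid orientation {o!r}")
    if c1 != c2:
        return "translocation"
    if (p1 > p2) or (p1 == p2 and o1 == "-"):  # orient by genomic order
        (p1, o1), (p2, o2) = (p2, o2), (p1, o1)
    if (o1, o2) == ("+", "-"):
        return "deletion"
    if (o1, o2) == ("-", "+"):
        return "duplication"
    return "inversion"


def detect_broken_genes(svs: pd.DataFrame, genes: pd.DataFrame,
                        min_support: int = 15) -> list[str]:
    """Genes hit by an SV breakpoint with support strictly above the cutoff.

    ``svs`` is BEDPE-like (chrom1/pos1/chrom2/pos2/supporting_reads); ``genes``
    has chrom/start/end/name with 1-based inclusive intervals.
    """
    g = genes.copy()
    if not g.sort_values(["chrom", "start"]).equals(g.reset_index(drop=True)):
        warnings.warn("gene table not sorted; sorting internally", stacklevel=2)
        g = g.sort_values(["chrom", "start"]).reset_index(drop=True)
    keep = svs[svs["supporting_reads"] > min_support]
    hits: list[str] = []
    for _, gene in g.iterrows():
        bp_in = ((keep["chrom1"] == gene["chrom"])
                 & keep["pos1"].between(gene["start"], gene["end"])) | (
                (keep["chrom2"] == gene["chrom"])
                 & keep["pos2"].between(gene["start"], gene["end"]))
        if bp_in.any():
            hits.append(gene["name"])
    return hits
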
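"""Simplified subclonal reconstruction for paired tumor components.

Mutations are mapped to cancer-cell fractions (CCF) with the standard
purity/copy-number transform, clustered across the two components of a tumor
with a binomial-mixture EM (model size chosen by BIC), and arranged into a
clone tree rooted at the clonal population C1. On genome-doubled tumors
(modal ploidy > 3), mutations on balanced A2B2 segments are timed relative to
the doubling event from their expected allele fractions (multiplicity 2 before
doubling vs 1 after), and the doubling is placed in a clone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .segments import SegmentProfile

# ---------------------------------------------------------------------------
# CCF transform


def compute_ccf(vaf, total_cn, minor_cn, purity: float, multiplicity,
                clip_max: float = 1.2):
    """Cancer-cell fraction of a mutation.

    ``ccf = vaf * (purity * total_cn + 2 * (1 - purity)) / (purity * m)`` for
    a mutation on ``m`` of the segment's alleles. Values are clipped to
    ``[0, clip_max]``; use :func:`ccf_overflow` to flag clipped entries.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    m = np.asarray(multiplicity, dtype=float)
    if np.any(m < 1):
        raise ValueError("multiplicity must be >= 1")
    major = np.asarray(total_cn, dtype=float) - np.asarray(minor_cn, dtype=float)
    if np.any(m > major + np.asarray(minor_cn, dtype=float)):
        raise ValueError("multiplicity exceeds total copy number")
    raw = (np.asarray(vaf, dtype=float)
           * (purity * np.asarray(total_cn, dtype=float) + 2.0 * (1.0 - purity))
           / (purity * m))
    return np.clip(raw, 0.0, clip_max)


def ccf_overflow(vaf, total_cn, purity: float, multiplicity,
                 clip_max: float = 1.2):
    raw = (np.asarray(vaf, float)
           * (purity * np.asarray(total_cn, float) + 2.0 * (1.0 - purity))
           / (purity * np.asarray(multiplicity, float)))
    return raw > clip_max


def estimate_multiplicity(vaf, total_cn, purity: float, major_cn):
    """Rounded allele count carrying the mutation, clipped to [1, major]."""
    raw = (np.asarray(vaf, float)
           * (purity * np.asarray(total_cn, float) + 2.0 * (1.0 - purity))
           / purity)
    return np.clip(np.round(raw), 1, np.asarray(major_cn, float)).astype(int)


def vaf_factor(total_cn, purity: float, multiplicity):
    """q such that expected VAF = ccf * q."""
    return (purity * np.asarray(multiplicity, float)
            / (purity * np.asarray(total_cn, float) + 2.0 * (1.0 - purity)))


# ---------------------------------------------------------------------------
# binomial-mixture clustering of paired CCFs


@dataclass
class CloneNode:
    clone_id: str
    parent: str | None
    ccf: dict                       # sample -> CCF
    mutations: list = field(default_factory=list)
    doubling_flag: bool = False
    signature_proportions: dict | None = None


class BinomialMixtureCCF(BaseEstimator):
    """EM mixture over paired-sample CCFs with binomial read likelihoods.

    Input rows carry (alt, depth, q) per sample, where q maps CCF to expected
    VAF (``vaf = ccf * q``). Cluster CCFs are updated with a method-of-moments
    step inside the EM loop (the exact M-step has no closed form when q varies
    by mutation). The component count is chosen by BIC over ``k_range``.
    """

    def __init__(self, k_range=range(1, 9), n_restarts: int = 10,
                 max_iter: int = 200, tol: float = 1e-6,
                 random_state: int = 0):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _loglik_matrix(alt, depth, q, phi):
        # (n, k) binomial log-likelihood summed over samples
        n, s = alt.shape
        k = phi.shape[0]
        ll = np.zeros((n, k))
        for c in range(k):
            p = np.clip(phi[c][None, :] * q, 1e-6, 1 - 1e-6)
            ll[:, c] = binom.logpmf(alt, depth, p).sum(axis=1)
        return ll

    def _em(self, alt, depth, q, k, rng):
        n, s = alt.shape
        ccf_hat = np.clip(alt / np.maximum(depth, 1) / np.maximum(q, 1e-9),
                          0.0, 1.2)
        phi = ccf_hat[rng.choice(n, size=k, replace=False)].copy()
        pi = np.full(k, 1.0 / k)
        prev = -np.inf
        for _ in range(self.max_iter):
            ll = self._loglik_matrix(alt, depth, q, phi) + np.log(pi + 1e-12)
            norm = logsumexp(ll, axis=1)
            resp = np.exp(ll - norm[:, None])
            total = float(norm.sum())
            pi = resp.mean(axis=0) + 1e-12
            pi /= pi.sum()
            for c in range(k):
                w = resp[:, c][:, None]
                num = (w * alt).sum(axis=0)
                den = (w * depth * q).sum(axis=0) + 1e-12
                phi[c] = np.clip(num / den, 0.0, 1.05)
            if total - prev < self.tol * (1 + abs(total)):
                break
            prev = total
        return phi, pi, total, resp

    def fit(self, table: pd.DataFrame):
        samples = sorted({c[4:] for c in table.columns if c.startswith("alt_")})
        alt = table[[f"alt_{s}" for s in samples]].to_numpy(dtype=float)
        depth = table[[f"depth_{s}" for s in samples]].to_numpy(dtype=float)
        q = table[[f"q_{s}" for s in samples]].to_numpy(dtype=float)
        rng = np.random.default_rng(self.random_state)
        n = len(table)

        best = None
        records = []
        for k in self.k_range:
            if k > n:
                break
            run_best = None
            for _ in range(self.n_restarts):
                phi, pi, ll, resp = self._em(alt, depth, q, k, rng)
                if run_best is None or ll > run_best[2]:
                    run_best = (phi, pi, ll, resp)
            n_params = k * len(samples) + (k - 1)
            bic = -2.0 * run_best[2] + n_params * np.log(n)
            records.append((k, run_best[2], bic))
            if best is None or bic < best[0]:
                best = (bic, k, run_best)
        self.bic_table_ = pd.DataFrame(records, columns=["k", "loglik", "bic"])
        self.n_clusters_ = best[1]
        phi, pi, ll, resp = best[2]
        self.cluster_ccfs_ = pd.DataFrame(phi, columns=samples)
        self.weights_ = pi
        self.labels_ = np.argmax(resp, axis=1)
        self.samples_ = samples
        return self

    def fit_predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.fit(table).labels_


def build_ccf_table(sample_a: pd.DataFrame, sample_b: pd.DataFrame,
                    purity_a: float = 1.0, purity_b: float = 1.0,
                    total_cn: int = 2, multiplicity: int = 1) -> pd.DataFrame:
    """Join two per-component mutation tables on mutation id.

    A mutation absent from one component gets zero alt reads at that
    component's median depth (it was covered but not observed).
    """
    frames = {}
    for name, df, purity in (("a", sample_a, purity_a), ("b", sample_b, purity_b)):
        d = df.set_index("id")
        depth = d["alt_count"] + d["ref_count"]
        frames[name] = pd.DataFrame({
            f"alt_{name}": d["alt_count"], f"depth_{name}": depth,
            f"q_{name}": vaf_factor(total_cn, purity, multiplicity)})
    out = frames["a"].join(frames["b"], how="outer")
    for name, df in (("a", sample_a), ("b", sample_b)):
        med = int((df["alt_count"] + df["ref_count"]).median())
        out[f"depth_{name}"] = out[f"depth_{name}"].fillna(med)
        out[f"alt_{name}"] = out[f"alt_{name}"].fillna(0)
        out[f"q_{name}"] = out[f"q_{name}"].fillna(out[f"q_{name}"].median())
    return out


def cluster_clones(ccf_table: pd.DataFrame, tol: float = 0.05,
                   min_mutations: int = 50, random_state: int = 0,
                   **params) -> list[CloneNode]:
    """Cluster paired CCFs into clones and arrange them into a tree.

    The cluster nearest (1, 1) becomes the clonal population C1; every other
    clone is attached to the most specific placed node whose CCF dominates it
    (within ``tol``) in every sample and whose remaining capacity (parent CCF
    minus already-attached children) admits it — otherwise to C1 directly.
    Fewer than ``min_mutations`` input mutations yield a single flagged clone.
    """
    if len(ccf_table) < min_mutations:
        warnings.warn("fewer than 50 mutations: single-clone fallback",
                      stacklevel=2)
        samples = sorted({c[4:] for c in ccf_table.columns
                          if c.startswith("alt_")})
        return [CloneNode("C1", None, {s: 1.0 for s in samples},
                          list(ccf_table.index))]
    est = BinomialMixtureCCF(random_state=random_state, **params).fit(ccf_table)
    ccfs = est.cluster_ccfs_
    samples = est.samples_
    order = np.argsort(-ccfs.sum(axis=1).to_numpy(), kind="stable")

    nodes: list[CloneNode] = []
    capacity: dict[str, np.ndarray] = {}
    for rank, c in enumerate(order):
        members = list(ccf_table.index[est.labels_ == c])
        ccf = {s: float(ccfs.loc[c, s]) for s in samples}
        cid = f"C{rank + 1}"
        if rank == 0:
            nodes.append(CloneNode(cid, None, ccf, members))
            capacity[cid] = np.array([ccf[s] for s in samples])
            continue
        vec = np.array([ccf[s] for s in samples])
        parent = nodes[0].clone_id
        best_sum = np.inf
        for node in nodes:
            pvec = np.array([node.ccf[s] for s in samples])
            if np.all(pvec >= vec - tol) and np.all(capacity[node.clone_id] >= vec - tol):
                if pvec.sum() < best_sum:
                    best_sum, parent = pvec.sum(), node.clone_id
        capacity[parent] = capacity[parent] - vec
        nodes.append(CloneNode(cid, parent, ccf, members))
        capacity[cid] = vec.copy()
    return nodes


# ---------------------------------------------------------------------------
# shared events between paired components


@dataclass
class SharedEventReport:
    table: pd.DataFrame  # per class: n_shared, n_a_private, n_b_private, fractions


def _match_point_events(a: pd.DataFrame, b: pd.DataFrame) -> int:
    key = ["chrom", "pos", "ref", "alt"]
    ka = set(map(tuple, a[key].itertuples(index=False)))
    kb = set(map(tuple, b[key].itertuples(index=False)))
    return len(ka & kb), len(ka), len(kb)


def _match_cna(a: pd.DataFrame, b: pd.DataFrame, min_overlap: float) -> tuple:
    used = np.zeros(len(b), dtype=bool)
    n_shared = 0
    for _, sa in a.iterrows():
        la = sa["end"] - sa["start"] + 1
        for j, sb in b.iterrows():
            if used[b.index.get_loc(j)] or sb["chrom"] != sa["chrom"]:
                continue
            if (sa["major_cn"], sa["minor_cn"]) != (sb["major_cn"], sb["minor_cn"]):
                continue
            ov = min(sa["end"], sb["end"]) - max(sa["start"], sb["start"]) + 1
            lb = sb["end"] - sb["start"] + 1
            if ov > 0 and ov >= min_overlap * la and ov >= min_overlap * lb:
                used[b.index.get_loc(j)] = True
                n_shared += 1
                break
    return n_shared, len(a), len(b)


def _match_sv(a: pd.DataFrame, b: pd.DataFrame, window: int) -> tuple:
    used = np.zeros(len(b), dtype=bool)
    n_shared = 0
    for _, sa in a.iterrows():
        for idx, (_, sb) in enumerate(b.iterrows()):
            if used[idx]:
                continue
            if (sa["chrom1"] == sb["chrom1"] and sa["chrom2"] == sb["chrom2"]
                    and abs(sa["pos1"] - sb["pos1"]) <= window
                    and abs(sa["pos2"] - sb["pos2"]) <= window):
                used[idx] = True
                n_shared += 1
                break
    return n_shared, len(a), len(b)


def shared_event_fractions(events_a: dict, events_b: dict,
                           cna_overlap: float = 0.5,
                           sv_window: int = 1_000) -> SharedEventReport:
    """Shared / private event counts per class for one tumor's two components.

    ``events_a``/``events_b`` map class names (``snv``, ``indel``, ``cna``,
    ``sv``) to tables. SNVs/indels match on (chrom, pos, ref, alt); CNA
    segments on identical genotype with reciprocal overlap >= ``cna_overlap``;
    SVs when both breakpoints agree within ``sv_window``. The headline
    ``shared_fraction`` is the Jaccard index |A∩B| / |A∪B|; per-sample
    fractions are reported alongside.
    """
    rows = []
    for cls in sorted(set(events_a) | set(events_b)):
        a = events_a.get(cls)
        b = events_b.get(cls)
        a = a if a is not None else pd.DataFrame()
        b = b if b is not None else pd.DataFrame()
        if len(a) == 0 and len(b) == 0:
            rows.append((cls, 0, 0, 0, float("nan"), float("nan"), float("nan")))
            continue
        if cls in ("snv", "indel"):
            shared, na, nb = _match_point_events(a, b)
        elif cls == "cna":
            shared, na, nb = _match_cna(a, b, cna_overlap)
        elif cls == "sv":
            shared, na, nb = _match_sv(a, b, sv_window)
        else:
            raise ValueError(f"unknown event class {cls!r}")
        union = na + nb - shared
        rows.append((cls, shared, na - shared, nb - shared,
                     shared / union if union else float("nan"),
                     shared / na if na else float("nan"),
                     shared / nb if nb else float("nan")))
    table = pd.DataFrame(rows, columns=[
        "class", "n_shared", "n_a_private", "n_b_private",
        "shared_fraction", "fraction_of_a", "fraction_of_b"])
    return SharedEventReport(table)


# ---------------------------------------------------------------------------
# genome-doubling timing


def doubling_expected_vafs(purity: float) -> tuple[float, float]:
    """Expected VAFs on an A2B2 segment before/after genome doubling.

    A pre-doubling mutation sits on two of four alleles, a post-doubling one
    on a single allele: at purity p the expectations are
    ``2p / (4p + 2(1-p))`` and ``p / (4p + 2(1-p))`` — 0.5 and 0.25 in a pure
    tumor.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    denom = 4.0 * purity + 2.0 * (1.0 - purity)
    return 2.0 * purity / denom, purity / denom


@dataclass
class DoublingTiming:
    per_mutation: pd.DataFrame      # adds a 'timing' column (before/after)
    v_before: float
    v_after: float
    doubling_clone: str | None
    available: bool = True
    reason: str | None = None


def time_genome_doubling(mutations: pd.DataFrame, purity: float,
                         profile: SegmentProfile | None = None,
                         clone_order: list | None = None) -> DoublingTiming:
    """Classify A2B2-segment mutations as pre- or post-doubling.

    Each mutation is assigned to the expected VAF (before: multiplicity 2,
    after: multiplicity 1) with the higher binomial likelihood. When clone
    labels are present, the doubling event is placed in the earliest clone
    (given ``clone_order``, root first) whose A2B2 mutations are predominantly
    pre-doubling (> 50%).
    """
    muts = mutations.copy()
    if profile is not None:
        if profile.modal_ploidy <= 3:
            return DoublingTiming(pd.DataFrame(), *doubling_expected_vafs(purity),
                                  None, False, "modal ploidy <= 3")
        a2b2 = profile.segments[(profile.segments["major_cn"] == 2)
                                & (profile.segments["minor_cn"] == 2)]
        if a2b2.empty:
            return DoublingTiming(pd.DataFrame(), *doubling_expected_vafs(purity),
                                  None, False, "no A2B2 segments")
        keep = np.zeros(len(muts), dtype=bool)
        for _, seg in a2b2.iterrows():
            keep |= ((muts["chrom"] == seg["chrom"])
                     & muts["pos"].between(seg["start"], seg["end"])).to_numpy()
        muts = muts[keep].copy()
    v_before, v_after = doubling_expected_vafs(purity)
    depth = (muts["alt_count"] + muts["ref_count"]).to_numpy()
    alt = muts["alt_count"].to_numpy()
    ll_b = binom.logpmf(alt, depth, v_before)
    ll_a = binom.logpmf(alt, depth, v_after)
    muts["timing"] = np.where(ll_b >= ll_a, "before", "after")

    doubling_clone = None
    if "clone" in muts.columns and len(muts):
        order = clone_order or sorted(muts["clone"].dropna().unique())
        for clone in order:
            sub = muts[muts["clone"] == clone]
            if len(sub) and (sub["timing"] == "before").mean() > 0.5:
                doubling_clone = clone
                break
    return DoublingTiming(muts, v_before, v_after, doubling_clone)


# ---------------------------------------------------------------------------
# per-clone signature proportions


def clone_signature_proportions(assignments: pd.DataFrame,
                                min_mutations: int = 20) -> pd.DataFrame:
    """Fraction of each fitted signature within every clone's mutation set.

    ``assignments`` needs ``clone`` and ``signature`` columns (the latter from
    the per-mutation signature assignment); ``unassigned`` mutations are
    excluded with a reported count, clones with no mutations are dropped, and
    clones below ``min_mutations`` are flagged low-confidence.
    """
    labelled = assignments[assignments["signature"] != "unassigned"]
    n_excluded = len(assignments) - len(labelled)
    out = (labelled.groupby("clone")["signature"]
           .value_counts(normalize=True).unstack(fill_value=0.0))
    out["n_mutations"] = labelled.groupby("clone").size()
    out["low_confidence"] = out["n_mutations"] < min_mutations
    out.attrs["n_excluded_unassigned"] = n_excluded
    return out
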
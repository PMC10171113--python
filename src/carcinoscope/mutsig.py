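"""Mutational-signature deconvolution on the 96-channel catalog.

De novo extraction follows the Alexandrov NMF scheme: the catalog (channels x
samples) is factorized at a given rank under generalized Kullback-Leibler
loss, the fit is repeated over Monte-Carlo bootstrap resamples of each
sample's counts, bootstrap signatures are matched by cosine similarity, and
the reported signature is the average over bootstraps. Rank selection balances
bootstrap cluster cohesion (silhouette on 1-cosine) against reconstruction
residual; recovered signatures are labelled by cosine match to a reference
catalog clustered jointly with Ward linkage on 1-cosine distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_samples

from .channels import CHANNELS_96, channel_of, cosine


# ---------------------------------------------------------------------------
# catalog construction


def build_context_matrix(mutations: pd.DataFrame,
                         fasta: str | None = None) -> pd.DataFrame:
    """96 x samples count matrix from a mutation table.

    Accepts either a precomputed ``channel`` column, explicit flanking-base
    columns (``five``/``three``), or chrom/pos coordinates with a reference
    FASTA to fetch the trinucleotide context. Purine-reference SNVs are
    reverse-complemented onto the pyrimidine strand. Non-SNV rows (indels,
    multi-base alleles) are skipped; the count is reported in
    ``result.attrs['n_skipped']``.
    """
    samples = list(pd.unique(mutations["sample"]))
    mat = pd.DataFrame(0, index=list(CHANNELS_96), columns=samples, dtype=int)
    n_skipped = 0
    fa = None
    if fasta is not None:
        from pyfaidx import Fasta
        fa = Fasta(fasta)
    for _, row in mutations.iterrows():
        ref, alt = str(row.get("ref", "")), str(row.get("alt", ""))
        if "channel" in mutations.columns and isinstance(row["channel"], str):
            ch = row["channel"]
        elif len(ref) == 1 and len(alt) == 1 and ref != alt:
            if "five" in mutations.columns:
                five, three = row["five"], row["three"]
            elif fa is not None:
                seq = fa[str(row["chrom"])][int(row["pos"]) - 2:
                                            int(row["pos"]) + 1].seq.upper()
                five, three = seq[0], seq[2]
            else:
                n_skipped += 1
                continue
            try:
                ch = channel_of(ref, alt, five, three)
            except ValueError:
                n_skipped += 1
                continue
        else:
            n_skipped += 1
            continue
        mat.loc[ch, row["sample"]] += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-SNV or malformed records",
                      stacklevel=2)
    mat.attrs["n_skipped"] = n_skipped
    return mat


# ---------------------------------------------------------------------------
# NMF with Monte-Carlo bootstrap


@dataclass
class SignatureSet:
    """Fitted signatures (96 x k, columns sum to 1) and exposures (k x S)."""

    W: pd.DataFrame
    H: pd.DataFrame
    k: int
    stability: np.ndarray       # per-signature bootstrap cluster cohesion
    residual: float             # relative Frobenius reconstruction error
    labels: list = field(default_factory=list)


def _kl_refit_H(V: np.ndarray, W: np.ndarray, n_iter: int = 500,
                tol: float = 1e-8) -> np.ndarray:
    """Multiplicative KL updates for H with W fixed."""
    k, s = W.shape[1], V.shape[1]
    H = np.full((k, s), V.sum() / (k * s) + 1e-9)
    wsum = W.sum(axis=0)[:, None] + 1e-12
    prev = np.inf
    for _ in range(n_iter):
        WH = W @ H + 1e-12
        H *= (W.T @ (V / WH)) / wsum
        err = float(np.linalg.norm(V - W @ H))
        if prev - err < tol * (1 + err):
            break
        prev = err
    return H


class SignatureNMF(BaseEstimator):
    """Bootstrap-averaged KL-NMF signature extraction (sklearn-style).

    Each bootstrap multinomially resamples every sample's mutation counts and
    refits the factorization (``n_restarts`` random restarts per fit, best
    kept); bootstrap signatures are matched to the first run by greedy cosine
    pairing, averaged per channel, and the exposures are refit on the original
    catalog with the averaged signatures held fixed.
    """

    def __init__(self, n_signatures: int = 2, n_bootstrap: int = 1,
                 n_restarts: int = 10, max_iter: int = 600,
                 random_state: int = 0):
        self.n_signatures = n_signatures
        self.n_bootstrap = n_bootstrap
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def _fit_once(self, V: np.ndarray, seed: int) -> tuple[np.ndarray, float]:
        best_w, best_err = None, np.inf
        for r in range(self.n_restarts):
            model = NMF(n_components=self.n_signatures, init="random",
                        solver="mu", beta_loss="kullback-leibler",
                        max_iter=self.max_iter, tol=1e-6,
                        random_state=seed + 1000 * r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = model.fit_transform(V)
            err = model.reconstruction_err_
            if err < best_err:
                best_w, best_err = w, err
        w = best_w / (best_w.sum(axis=0, keepdims=True) + 1e-12)
        return w, best_err

    def fit(self, catalog: pd.DataFrame):
        if self.n_signatures < 1:
            raise ValueError("rank must be >= 1")
        cat = catalog.loc[:, catalog.sum(axis=0) > 0]
        if cat.shape[1] < catalog.shape[1]:
            warnings.warn("dropping empty sample columns", stacklevel=2)
        if self.n_signatures >= cat.shape[1]:
            warnings.warn("rank >= number of samples; fit may be degenerate",
                          stacklevel=2)
        V = cat.to_numpy(dtype=float)
        rng = np.random.default_rng(self.random_state)

        w_ref, _ = self._fit_once(V, int(rng.integers(2 ** 31)))
        boots = [w_ref]
        for _ in range(self.n_bootstrap - 1):
            Vb = np.column_stack([
                rng.multinomial(int(V[:, j].sum()),
                                V[:, j] / V[:, j].sum())
                for j in range(V.shape[1])]).astype(float)
            wb, _ = self._fit_once(Vb, int(rng.integers(2 ** 31)))
            # greedy cosine pairing to the reference run's signatures
            sim = np.array([[cosine(w_ref[:, i], wb[:, j])
                             for j in range(self.n_signatures)]
                            for i in range(self.n_signatures)])
            matched = np.zeros_like(wb)
            used: set[int] = set()
            for i in np.argsort(-sim.max(axis=1)):
                j = int(max((j for j in range(self.n_signatures)
                             if j not in used), key=lambda j: sim[i, j]))
                used.add(j)
                matched[:, i] = wb[:, j]
            boots.append(matched)

        stack = np.stack(boots)                      # (B, 96, k)
        W = stack.mean(axis=0)
        W = W / W.sum(axis=0, keepdims=True)
        H = _kl_refit_H(V, W)

        self.stability_ = self._cohesion(stack)
        self.components_ = W
        self.W_ = pd.DataFrame(W, index=cat.index,
                               columns=[f"S{i + 1}" for i in range(self.n_signatures)])
        self.H_ = pd.DataFrame(H, index=self.W_.columns, columns=cat.columns)
        Vn = V
        self.residual_ = float(np.linalg.norm(Vn - W @ H) / np.linalg.norm(Vn))
        return self

    @staticmethod
    def _cohesion(stack: np.ndarray) -> np.ndarray:
        """Per-signature silhouette of the matched bootstrap signatures
        under 1-cosine distance."""
        b, _, k = stack.shape
        if b < 2 or k < 2:
            return np.ones(k)
        X = np.concatenate([stack[i].T for i in range(b)])  # (b*k, 96)
        labels = np.tile(np.arange(k), b)
        norm = np.linalg.norm(X, axis=1, keepdims=True) + 1e-12
        D = 1.0 - (X / norm) @ (X / norm).T
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2, 0.0, None)
        sil = silhouette_samples(D, labels, metric="precomputed")
        return np.array([sil[labels == j].mean() for j in range(k)])

    def transform(self, catalog: pd.DataFrame) -> pd.DataFrame:
        """Exposures of new samples under the fitted signatures."""
        H = _kl_refit_H(catalog.to_numpy(dtype=float), self.components_)
        return pd.DataFrame(H, index=self.W_.columns, columns=catalog.columns)


def nmf_bootstrap(catalog: pd.DataFrame, k: int, n_bootstrap: int = 1,
                  seed: int = 0, **params) -> SignatureSet:
    """Functional wrapper over :class:`SignatureNMF`."""
    est = SignatureNMF(n_signatures=k, n_bootstrap=n_bootstrap,
                       random_state=seed, **params).fit(catalog)
    return SignatureSet(est.W_, est.H_, k, est.stability_, est.residual_)


# ---------------------------------------------------------------------------
# rank selection


def select_rank(catalog: pd.DataFrame, k_range=range(2, 11),
                n_bootstrap: int = 50, seed: int = 0,
                cohesion_min: float = 0.80, residual_floor: float = 0.05,
                **params) -> tuple[int, pd.DataFrame]:
    """Choose the number of signatures by stability and residual decrease.

    For each rank the bootstrap cluster cohesion (mean silhouette on 1-cosine)
    and the relative reconstruction residual are computed; the chosen rank is
    the largest whose cohesion is >= ``cohesion_min`` and whose residual
    improves on the previous rank by at least ``residual_floor`` (relative).
    If no rank is stable the most cohesive one is returned and the diagnostics
    table is flagged (``attrs['unstable'] = True``).
    """
    ks = sorted(k_range)
    prev_resid = nmf_bootstrap(catalog, 1, 1, seed, **params).residual
    rows = []
    for k in ks:
        fit = nmf_bootstrap(catalog, k, n_bootstrap, seed, **params)
        improv = (prev_resid - fit.residual) / max(prev_resid, 1e-12)
        rows.append((k, float(fit.stability.mean()), fit.residual, improv))
        prev_resid = fit.residual
    diag = pd.DataFrame(rows, columns=["k", "cohesion", "residual",
                                       "residual_improvement"])
    ok = diag[(diag["cohesion"] >= cohesion_min)
              & (diag["residual_improvement"] >= residual_floor)]
    if ok.empty:
        diag.attrs["unstable"] = True
        return int(diag.loc[diag["cohesion"].idxmax(), "k"]), diag
    diag.attrs["unstable"] = False
    return int(ok["k"].max()), diag


# ---------------------------------------------------------------------------
# reference matching


@dataclass
class MatchResult:
    labels: list
    similarity: pd.DataFrame     # fitted signatures x reference signatures
    linkage: np.ndarray          # Ward linkage of {fitted + reference} columns
    leaves: list


def match_to_reference(W: pd.DataFrame, reference: pd.DataFrame) -> MatchResult:
    """Label fitted signatures by their best-cosine reference match.

    Also clusters the union of fitted and reference profiles hierarchically
    (1-cosine distance, Ward linkage). Channel order must match the canonical
    layout exactly; a mismatch raises instead of silently reordering.
    """
    if list(W.index) != list(reference.index):
        raise ValueError("channel order mismatch between signatures and "
                         "reference matrix")
    sim = pd.DataFrame(
        [[cosine(W[c].to_numpy(), reference[r].to_numpy())
          for r in reference.columns] for c in W.columns],
        index=W.columns, columns=reference.columns)
    labels = [(sim.loc[c].idxmax(), float(sim.loc[c].max())) for c in W.columns]

    joint = pd.concat([W, reference], axis=1)
    X = joint.to_numpy(dtype=float).T
    norm = np.linalg.norm(X, axis=1, keepdims=True) + 1e-12
    D = np.clip(1.0 - (X / norm) @ (X / norm).T, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform((D + D.T) / 2, checks=False), method="ward")
    return MatchResult(labels, sim, Z, list(joint.columns))


# ---------------------------------------------------------------------------
# per-mutation assignment


def assign_mutations(mutations: pd.DataFrame, W: pd.DataFrame,
                     H: pd.DataFrame) -> pd.DataFrame:
    """Most probable signature per mutation with its posterior.

    P(sig j | channel c, sample s) ∝ W[c, j] * H[j, s]. Ties go to the lower
    signature index and are flagged; channels with zero total weight are
    labelled ``unassigned``.
    """
    out = mutations.copy()
    sigs = list(W.columns)
    labels, posts, ties = [], [], []
    for _, row in out.iterrows():
        w = W.loc[row["channel"]].to_numpy() * H[row["sample"]].to_numpy()
        tot = w.sum()
        if tot <= 0:
            labels.append("unassigned")
            posts.append(np.nan)
            ties.append(False)
            continue
        p = w / tot
        j = int(np.argmax(p))
        labels.append(sigs[j])
        posts.append(float(p[j]))
        ties.append(bool((p == p[j]).sum() > 1))
    out["signature"] = labels
    out["posterior"] = posts
    out["tie"] = ties
    return out
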
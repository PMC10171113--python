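"""Synthetic reference signature matrix in the COSMIC v2 96-channel layout.

The real COSMIC v2 catalog is an external download; this module builds a
*synthetic* stand-in with the same layout (channels x signatures, columns
summing to 1) and the family structure the matching step relies on:

* ``Signature 1`` — clock-like deamination: C>T concentrated at NpCpG;
* ``Signature 2`` / ``Signature 13`` — APOBEC: C>T resp. C>G at TpC;
* ``Signature 3`` — BRCAness: near-flat across all 96 channels;
* ``Signature 6/15/20/26`` — the mismatch-repair-deficiency (MSI) family;
* a few broad fillers (5, 8, 17) so that matching is non-trivial.

Shapes are parametric caricatures, adequate for simulation and label-matching
tests; they are not the measured COSMIC profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .channels import BASES, CHANNELS_96, parse_channel

MSI_FAMILY = ("Signature 6", "Signature 15", "Signature 20", "Signature 26")
APOBEC_FAMILY = ("Signature 2", "Signature 13")
BRCA_FAMILY = ("Signature 3",)
AGE_FAMILY = ("Signature 1",)

FAMILY_OF = {
    **{s: "MSI" for s in MSI_FAMILY},
    **{s: "APOBEC" for s in APOBEC_FAMILY},
    **{s: "BRCAness" for s in BRCA_FAMILY},
    **{s: "age" for s in AGE_FAMILY},
}


def _profile(weight_fn, floor: float = 0.05) -> np.ndarray:
    w = np.array([weight_fn(*parse_channel(ch)) for ch in CHANNELS_96], float)
    w = w + floor * w.sum() / 96.0 if w.sum() > 0 else np.ones(96)
    return w / w.sum()


def synthetic_cosmic_v2_like() -> pd.DataFrame:
    """96 x 11 synthetic reference matrix, columns normalized to sum 1."""
    five_bias = {b: 1.0 + 0.1 * i for i, b in enumerate(BASES)}
    sigs = {
        # clock-like: C>T at NpCpG
        "Signature 1": _profile(
            lambda r, a, f, t: 10.0 if (r, a, t) == ("C", "T", "G") else 0.2
            if (r, a) == ("C", "T") else 0.0),
        # APOBEC C>T at TpC
        "Signature 2": _profile(
            lambda r, a, f, t: 12.0 if (r, a, f) == ("C", "T", "T") else 0.0,
            floor=0.03),
        # BRCAness: near-flat
        "Signature 3": _profile(lambda r, a, f, t: five_bias[f], floor=0.5),
        # flat-ish with T>C lean
        "Signature 5": _profile(
            lambda r, a, f, t: 3.0 if (r, a) == ("T", "C") else 1.0, floor=0.5),
        # MSI: C>T away from TpC, G-flank heavy
        "Signature 6": _profile(
            lambda r, a, f, t: (6.0 if f == "G" else 2.0)
            if (r, a) == ("C", "T") and f != "T"
            else (1.0 if (r, a) == ("C", "A") else 0.0)),
        # broad C>A
        "Signature 8": _profile(
            lambda r, a, f, t: 4.0 if (r, a) == ("C", "A") else 0.3, floor=0.2),
        # APOBEC C>G at TpC
        "Signature 13": _profile(
            lambda r, a, f, t: 12.0 if (r, a, f) == ("C", "G", "T") else 0.0,
            floor=0.03),
        # MSI: C>T with 3' T preference
        "Signature 15": _profile(
            lambda r, a, f, t: (8.0 if t == "T" else 2.0)
            if (r, a) == ("C", "T") and f != "T" else 0.0),
        # T>G at CpTpT
        "Signature 17": _profile(
            lambda r, a, f, t: 15.0 if (r, a, f, t) == ("T", "G", "C", "T")
            else 0.0, floor=0.04),
        # MSI: mixed C>T / C>A, A-flank heavy
        "Signature 20": _profile(
            lambda r, a, f, t: (5.0 if f == "A" else 1.5)
            if (r, a) == ("C", "T") and f != "T"
            else (2.0 if (r, a) == ("C", "A") else 0.0)),
        # MSI: T>C dominated
        "Signature 26": _profile(
            lambda r, a, f, t: 5.0 if (r, a) == ("T", "C") else 0.0, floor=0.15),
    }
    return pd.DataFrame(sigs, index=list(CHANNELS_96))


def write_reference_tsv(path: str = "synthetic_cosmic_v2_like.tsv") -> None:
    synthetic_cosmic_v2_like().rename_axis("channel").to_csv(path, sep="\t")


def load_reference(path: str | None = None) -> pd.DataFrame:
    """Load a 96 x k reference matrix; default is the synthetic catalog.

    A TSV must carry the channel labels in its first column; the row order is
    checked against the canonical layout (never silently reordered — a
    mismatch raises).
    """
    if path is None:
        return synthetic_cosmic_v2_like()
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if list(tab.index) != list(CHANNELS_96):
        raise ValueError("reference matrix channel order does not match the "
                         "canonical 96-channel layout")
    return tab
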
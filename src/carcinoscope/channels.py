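"""The canonical 96 single-base-substitution channels.

A channel is a pyrimidine-normalized trinucleotide substitution class written
``5'[REF>ALT]3'``, e.g. ``T[C>T]A``. Substitutions with a purine reference are
reverse-complemented onto the pyrimidine strand. Channel order is the standard
COSMIC layout: the six substitutions C>A, C>G, C>T, T>A, T>C, T>G, each expanded
over the 16 flank pairs with the 5' base varying slowest (A, C, G, T).
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Pyrimidine-normalized channel for an SNV with its two flanking bases.

    Purine-reference mutations are mapped to the reverse-complement strand, so
    e.g. a G>T with 5' flank A and 3' flank C becomes ``G[C>A]T``.
    """
    ref, alt, five, three = (b.upper() for b in (ref, alt, five, three))
    if ref == alt or any(b not in COMPLEMENT for b in (ref, alt, five, three)):
        raise ValueError(f"not a valid SNV context: {five}[{ref}>{alt}]{three}")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


def parse_channel(channel: str) -> tuple[str, str, str, str]:
    """Split ``5'[REF>ALT]3'`` into (ref, alt, five, three)."""
    if len(channel) != 7 or channel[1] != "[" or channel[6] not in BASES:
        raise ValueError(f"malformed channel {channel!r}")
    return channel[2], channel[4], channel[0], channel[6]


def is_tpc_cd(channel: str) -> bool:
    """True for the APOBEC-type channels: C>A/C>G/C>T at a TpC dinucleotide."""
    ref, alt, five, _ = parse_channel(channel)
    return ref == "C" and five == "T" and alt in ("A", "G", "T")


def counts_vector(channels: "list[str] | np.ndarray") -> np.ndarray:
    """96-vector of counts from an iterable of channel labels."""
    out = np.zeros(96, dtype=int)
    for ch in channels:
        out[CHANNEL_INDEX[ch]] += 1
    return out


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; 0 when either vector is all-zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))
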
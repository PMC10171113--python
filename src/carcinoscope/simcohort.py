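"""Synthetic paired-component tumor cohorts with known ground truth.

Every downstream stage of the pipeline (copy-number inference, signature
deconvolution, scar phenotyping, clonal reconstruction) is tested against
cohorts generated here: two components per tumor share a clonal trunk, and
the planted exposures, clones, segment profiles, kataegis clusters, tandem
duplications and unstable microsatellite sites are serialized as truth.

Randomness: one master seed; each simulator draws from a named substream so
that adding a new simulator never perturbs existing streams.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .channels import CHANNELS_96, parse_channel
from .genome import GenomeModel, miniature_genome
from .segments import SEGMENT_COLUMNS, SegmentProfile
from .signals import BinnedSignal, expected_baf, expected_rc

MUTATION_COLUMNS = ["id", "sample", "chrom", "pos", "ref", "alt",
                    "channel", "alt_count", "ref_count", "vaf"]

DEFAULT_DEPTH = 77  # tumor median coverage emulated by the read model


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-simulator random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# configuration / truth containers


@dataclass
class KataegisSpec:
    n_clusters: int = 2
    cluster_size: int = 8
    max_span: int = 2_000  # bp
    sv_linked: bool = True


@dataclass
class MsiSpec:
    n_sites: int = 200
    unstable_fraction: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the cohort the pipeline targets: paired components
    sharing a clonal trunk, purity 20-100%, ploidy 2-5, ~77x coverage.
    """

    n_tumors: int = 3
    components_per_tumor: int = 2
    purity_range: tuple[float, float] = (0.4, 1.0)
    ploidy_choices: tuple[int, ...] = (2, 3, 4)
    signature_exposures: dict = field(
        default_factory=lambda: {"Signature 1": 0.6, "Signature 3": 0.4})
    mutation_burden: int = 4_000
    shared_event_fraction: float = 0.6
    n_lst_events: int = 4
    n_tandem_dups: int = 10
    kataegis_spec: KataegisSpec = field(default_factory=KataegisSpec)
    msi_spec: MsiSpec = field(default_factory=MsiSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.kataegis_spec, dict):
            self.kataegis_spec = KataegisSpec(**self.kataegis_spec)
        if isinstance(self.msi_spec, dict):
            self.msi_spec = MsiSpec(**self.msi_spec)
        total = float(sum(self.signature_exposures.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError("signature exposures must sum to 1")
        if not 0.0 <= self.shared_event_fraction <= 1.0:
            raise ValueError("shared_event_fraction must lie in [0, 1]")
        lo, hi = self.purity_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")

    @classmethod
    def msi_preset(cls, **kw) -> "SimConfig":
        """Hypermutated, genomically quiet, MSI-signature-driven tumors."""
        kw.setdefault("signature_exposures",
                      {"Signature 6": 0.5, "Signature 26": 0.3, "Signature 1": 0.2})
        kw.setdefault("mutation_burden", 20_000)
        kw.setdefault("n_lst_events", 0)
        kw.setdefault("n_tandem_dups", 0)
        kw.setdefault("ploidy_choices", (2,))
        kw.setdefault("kataegis_spec", KataegisSpec(n_clusters=0))
        kw.setdefault("msi_spec", MsiSpec(n_sites=200, unstable_fraction=0.5))
        return cls(**kw)

    @classmethod
    def brcaness_preset(cls, **kw) -> "SimConfig":
        """LST-rich, tandem-duplication-rich, flat-signature tumors."""
        kw.setdefault("signature_exposures",
                      {"Signature 3": 0.7, "Signature 1": 0.3})
        kw.setdefault("n_lst_events", 22)
        kw.setdefault("n_tandem_dups", 60)
        kw.setdefault("kataegis_spec", KataegisSpec(n_clusters=0))
        return cls(**kw)

    @classmethod
    def apobec_preset(cls, **kw) -> "SimConfig":
        """TpC-mutation-driven tumors with kataegis clusters near SVs."""
        kw.setdefault("signature_exposures",
                      {"Signature 2": 0.4, "Signature 13": 0.3, "Signature 1": 0.3})
        kw.setdefault("kataegis_spec", KataegisSpec(n_clusters=3))
        return cls(**kw)

    @classmethod
    def doubled_preset(cls, **kw) -> "SimConfig":
        """Genome-doubled tumors with A2B2 segments for doubling timing."""
        kw.setdefault("ploidy_choices", (4,))
        kw.setdefault("signature_exposures",
                      {"Signature 1": 0.5, "Signature 3": 0.5})
        return cls(**kw)


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside each simulated tumor."""

    exposures: dict = field(default_factory=dict)       # sample -> {sig: frac}
    clones: list = field(default_factory=list)          # dicts: id/parent/ccf/mutations
    segment_profiles: dict = field(default_factory=dict)  # sample -> segment rows
    kataegis: list = field(default_factory=list)        # dicts chrom/start/end/sample
    tandem_dups: list = field(default_factory=list)
    unstable_sites: list = field(default_factory=list)
    purity: dict = field(default_factory=dict)
    ploidy: dict = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for clone in self.clones:
            for mid in clone["mutations"]:
                if mid in seen:
                    raise ValueError(f"mutation {mid} assigned to two clones")
                seen.add(mid)

    def to_json(self, path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# point mutations


def simulate_mutation_catalog(exposures, n_mut: int, ref_signatures: pd.DataFrame,
                              seed: int, genome: GenomeModel | None = None,
                              sample: str = "S1", depth: int = DEFAULT_DEPTH,
                              purity: float = 1.0, ccf: float = 1.0,
                              total_cn: int = 2, multiplicity: int = 1,
                              id_prefix: str | None = None) -> pd.DataFrame:
    """Draw SNVs whose 96-channel spectrum follows ``W @ exposures``.

    ``exposures`` is a simplex over the columns of ``ref_signatures`` (either a
    vector in column order or a {name: weight} mapping). Positions are uniform
    over the genome model; read counts follow the binomial VAF model at the
    given coverage.
    """
    genome = genome or miniature_genome()
    if isinstance(exposures, dict):
        vec = np.array([exposures.get(c, 0.0) for c in ref_signatures.columns])
    else:
        vec = np.asarray(exposures, dtype=float)
        if vec.size != ref_signatures.shape[1]:
            raise ValueError("exposures length does not match signature count")
    if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError("exposures must be a simplex (nonnegative, sum 1)")
    w = ref_signatures.to_numpy(dtype=float)
    w = w / w.sum(axis=0, keepdims=True)
    mix = w @ vec

    rng = substream(seed, f"mutations:{sample}")
    if n_mut == 0:
        return pd.DataFrame(columns=MUTATION_COLUMNS)
    chan_idx = rng.choice(96, size=n_mut, p=mix)
    chrom_lens = np.array([l for _, l in genome.chrom_lengths])
    chrom_ids = rng.choice(len(chrom_lens), size=n_mut,
                           p=chrom_lens / chrom_lens.sum())
    pos = (rng.random(n_mut) * chrom_lens[chrom_ids]).astype(np.int64) + 1

    exp_vaf = ccf * purity * multiplicity / (purity * total_cn + 2 * (1 - purity))
    depths = rng.poisson(depth, size=n_mut).clip(min=1)
    alt = rng.binomial(depths, exp_vaf)

    prefix = id_prefix if id_prefix is not None else sample
    recs = []
    for i in range(n_mut):
        ch = CHANNELS_96[chan_idx[i]]
        ref, alt_base, _, _ = parse_channel(ch)
        recs.append((f"{prefix}:m{i}", sample, genome.chroms[chrom_ids[i]],
                     int(pos[i]), ref, alt_base, ch, int(alt[i]),
                     int(depths[i] - alt[i]),
                     float(alt[i] / depths[i])))
    df = pd.DataFrame(recs, columns=MUTATION_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# copy-number forward model


def binned_signal_from_profile(profile: SegmentProfile, seed: int,
                               bin_size: int = 100_000,
                               reads_per_bin: float = 1_000.0,
                               het_spacing: int = 25_000,
                               het_depth: int = DEFAULT_DEPTH,
                               gc_bias: tuple[float, float] = (0.5, 0.0),
                               noiseless: bool = False) -> BinnedSignal:
    """Emit binned read counts (with GC bias) and het-site BAFs for a profile.

    ``gc_bias`` gives the (short-window, long-window) multiplicative slopes on
    GC fraction; read counts are Poisson around the lattice expectation unless
    ``noiseless``.
    """
    rng = substream(seed, "binned-signal")
    p, psi = profile.purity, profile.mean_ploidy
    bin_rows, het_rows = [], []
    for _, seg in profile.segments.iterrows():
        n_bins = max(1, int((seg["end"] - seg["start"] + 1) // bin_size))
        starts = seg["start"] + bin_size * np.arange(n_bins)
        r = float(expected_rc(seg["total_cn"], p, psi))
        b_unf = float(expected_baf(seg["major_cn"], seg["minor_cn"], p,
                                   folded=False))
        # per-bin GC: mostly independent bin-to-bin, with a weak long-range
        # wave so the two nested correction windows see distinct scales
        gc = (0.45 + 0.05 * rng.standard_normal(n_bins)
              + 0.02 * np.sin(starts / 7.3e6))
        gc = np.clip(gc, 0.2, 0.8)
        gc_long = pd.Series(gc).rolling(5, center=True, min_periods=1).mean().to_numpy()
        bias = (1.0 + gc_bias[0] * (gc - 0.45)) * (1.0 + gc_bias[1] * (gc_long - 0.45))
        lam = reads_per_bin * r * np.clip(bias, 0.05, None)
        raw = lam if noiseless else rng.poisson(lam).astype(float)
        for j in range(n_bins):
            end = starts[j] + bin_size - 1 if j < n_bins - 1 else seg["end"]
            bin_rows.append((seg["chrom"], int(starts[j]), int(end),
                             float(raw[j]), float(gc[j])))
        het_pos = np.arange(seg["start"] + het_spacing // 2, seg["end"],
                            het_spacing)
        for hp in het_pos:
            f = b_unf if rng.random() < 0.5 else 1.0 - b_unf
            d = het_depth if noiseless else max(1, int(rng.poisson(het_depth * r)))
            baf = f if noiseless else rng.binomial(d, min(max(f, 0.0), 1.0)) / d
            het_rows.append((seg["chrom"], int(hp), float(baf), int(d)))
    return BinnedSignal(
        bins=pd.DataFrame(bin_rows, columns=["chrom", "start", "end", "raw_rc", "gc"]),
        hets=pd.DataFrame(het_rows, columns=["chrom", "pos", "baf", "depth"]))


def simulate_segment_profile(ploidy: int, purity: float, n_lst_events: int,
                             small_variation_sizes=(), seed: int = 0,
                             genome: GenomeModel | None = None,
                             bin_size: int = 100_000,
                             **signal_kw) -> tuple[SegmentProfile, BinnedSignal]:
    """Plant exactly ``n_lst_events`` qualifying large-scale breaks.

    Each break separates two same-arm segments that are both >= 10 Mb after
    3-Mb smoothing; ``small_variation_sizes`` adds interstitial excursions (to
    exercise the smoothing filter) placed well away from the planted breaks.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    for sz in small_variation_sizes:
        if sz < bin_size:
            raise ValueError(f"bin size {bin_size} too coarse for a {sz} bp variation")
    genome = genome or miniature_genome()
    rng = substream(seed, "segment-profile")
    flank = 10_000_000

    arms = list(genome.arms())
    capacity = [max(0, arm.length // flank - 1) for arm in arms]
    if n_lst_events > sum(capacity):
        raise ValueError("too many LST events for this genome model")
    breaks_per_arm = [0] * len(arms)
    i = 0
    for _ in range(n_lst_events):
        while breaks_per_arm[i % len(arms)] >= capacity[i % len(arms)]:
            i += 1
        breaks_per_arm[i % len(arms)] += 1
        i += 1

    base = (ploidy - ploidy // 2, ploidy // 2)  # (major, minor)
    # three distinct aberrant states: a gain and a full-LOH loss. The LOH
    # segment pins the purity (its BAF is (1+p)/2), breaking the exact
    # "subtract one copy of each allele vs add contamination" alias that a
    # genome with minor_cn >= 1 everywhere would leave.
    gain = (base[0] + 1, base[1])
    loss = (base[0], 0) if base[1] > 0 else (base[0] + 2, 0)
    states = [base, gain, loss]
    rows = []
    for arm_i, (arm, k) in enumerate(zip(arms, breaks_per_arm)):
        free = arm.length - (k + 1) * flank
        parts = rng.dirichlet(np.ones(k + 1)) * free if k > 0 else np.array([free])
        lengths = (flank + parts).astype(np.int64)
        lengths = (lengths // bin_size) * bin_size
        lengths[-1] = arm.length - lengths[:-1].sum()
        pos = arm.start
        for j, ln in enumerate(lengths):
            # rotate the state cycle per arm so all three states occur
            # genome-wide even when arms carry single breaks
            a, b = states[(arm_i + j) % 3] if k > 0 else base
            rows.append([arm.chrom, pos, pos + int(ln) - 1, a + b, a, b])
            pos += int(ln)

    segs = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    # embed interstitial variations centered in the longest segments
    for sz in sorted(small_variation_sizes, reverse=True):
        sz = (int(sz) // bin_size) * bin_size
        lengths = segs["end"] - segs["start"] + 1
        host = lengths.idxmax()
        if lengths[host] < sz + 2 * flank:
            raise ValueError("no segment long enough to host the variation")
        seg = segs.loc[host]
        mid = (seg["start"] + seg["end"]) // 2
        v_start = int(mid - sz // 2)
        v_start = seg["start"] + ((v_start - seg["start"]) // bin_size) * bin_size
        v_end = v_start + sz - 1
        a, b = int(seg["major_cn"]), int(seg["minor_cn"])
        va, vb = (a, b - 1) if b > 0 else (a - 1, 0)
        pieces = [
            [seg["chrom"], seg["start"], v_start - 1, a + b, a, b],
            [seg["chrom"], v_start, v_end, va + vb, va, vb],
            [seg["chrom"], v_end + 1, seg["end"], a + b, a, b],
        ]
        segs = pd.concat([segs.drop(index=host),
                          pd.DataFrame(pieces, columns=SEGMENT_COLUMNS)],
                         ignore_index=True)
        segs = segs.sort_values(["chrom", "start"]).reset_index(drop=True)

    profile = SegmentProfile(segs, purity, genome)
    signal = binned_signal_from_profile(profile, seed=seed, bin_size=bin_size,
                                        **signal_kw)
    return profile, signal


# ---------------------------------------------------------------------------
# paired components


def simulate_paired_components(trunk_fraction: float, divergence_spec: dict | None = None,
                               seed: int = 0,
                               ref_signatures: pd.DataFrame | None = None,
                               genome: GenomeModel | None = None
                               ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Two components sharing a clonal trunk of mutations.

    ``divergence_spec`` keys (all optional): ``n_events`` total SNVs (default
    1000), ``exposures`` simplex, ``ccf_private_a``/``ccf_private_b`` (default
    0.6 / 0.5), ``purity`` per component, ``depth``.
    """
    if not 0.0 <= trunk_fraction <= 1.0:
        raise ValueError("trunk_fraction must lie in [0, 1]")
    from .refsigs import synthetic_cosmic_v2_like
    spec = dict(divergence_spec or {})
    n_events = int(spec.get("n_events", 1000))
    refs = ref_signatures if ref_signatures is not None else synthetic_cosmic_v2_like()
    exposures = spec.get("exposures", {"Signature 1": 1.0})
    purity = float(spec.get("purity", 1.0))
    depth = int(spec.get("depth", DEFAULT_DEPTH))
    ccf_a = float(spec.get("ccf_private_a", 0.6))
    ccf_b = float(spec.get("ccf_private_b", 0.5))
    genome = genome or miniature_genome()

    rng = substream(seed, "paired-components")
    is_trunk = rng.random(n_events) < trunk_fraction
    n_trunk = int(is_trunk.sum())
    n_private = n_events - n_trunk
    to_a = rng.random(n_private) < 0.5

    trunk = simulate_mutation_catalog(exposures, n_trunk, refs, seed, genome,
                                      sample="trunk", depth=depth, purity=purity,
                                      id_prefix="trunk")
    priv = simulate_mutation_catalog(exposures, n_private, refs, seed + 1,
                                     genome, sample="private", depth=depth,
                                     purity=purity, id_prefix="priv")
    priv_a = priv[to_a].copy()
    priv_b = priv[~to_a].copy()

    def _resample(df: pd.DataFrame, sample: str, ccf: float, stream: str) -> pd.DataFrame:
        df = df.copy()
        df["sample"] = sample
        r = substream(seed, stream)
        exp_vaf = ccf * purity / (purity * 2 + 2 * (1 - purity))
        d = r.poisson(depth, size=len(df)).clip(min=1)
        alt = r.binomial(d, exp_vaf)
        df["alt_count"], df["ref_count"] = alt, d - alt
        df["vaf"] = alt / d
        return df

    samp_a = pd.concat([_resample(trunk, "A", 1.0, "reads:A-trunk"),
                        _resample(priv_a, "A", ccf_a, "reads:A-priv")],
                       ignore_index=True)
    samp_b = pd.concat([_resample(trunk, "B", 1.0, "reads:B-trunk"),
                        _resample(priv_b, "B", ccf_b, "reads:B-priv")],
                       ignore_index=True)

    truth = SyntheticTruth(
        clones=[
            {"id": "C1", "parent": None, "ccf": {"A": 1.0, "B": 1.0},
             "mutations": list(trunk["id"])},
            {"id": "C2", "parent": "C1", "ccf": {"A": ccf_a, "B": 0.0},
             "mutations": list(priv_a["id"])},
            {"id": "C3", "parent": "C1", "ccf": {"A": 0.0, "B": ccf_b},
             "mutations": list(priv_b["id"])},
        ],
        purity={"A": purity, "B": purity},
    )
    truth.validate()
    return (samp_a.sort_values(["chrom", "pos"]).reset_index(drop=True),
            samp_b.sort_values(["chrom", "pos"]).reset_index(drop=True),
            truth)


# ---------------------------------------------------------------------------
# microsatellites


def simulate_msi_profile(n_sites: int, unstable_fraction: float,
                         reads_per_site: int = 100, seed: int = 0,
                         lengths=tuple(range(8, 21))
                         ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Paired tumor/normal microsatellite length-distribution tables.

    Stable sites draw tumor reads from the normal distribution; unstable sites
    draw from a shifted, broadened one. Returns (tumor, normal, unstable ids);
    tables are sites x length-bins read counts.
    """
    if not 0.0 <= unstable_fraction <= 1.0:
        raise ValueError("unstable_fraction must lie in [0, 1]")
    if reads_per_site < 10:
        warnings.warn("fewer than 10 reads per site: instability calls are "
                      "unreliable", stacklevel=2)
    rng = substream(seed, "msi")
    lengths = np.asarray(lengths)
    cols = [f"len{l}" for l in lengths]
    if n_sites == 0:
        empty = pd.DataFrame(columns=cols)
        return empty, empty, []

    n_unstable = int(round(n_sites * unstable_fraction))
    unstable = np.zeros(n_sites, dtype=bool)
    unstable[rng.choice(n_sites, size=n_unstable, replace=False)] = True

    t_rows, n_rows, ids = [], [], []
    for i in range(n_sites):
        mode = int(rng.integers(lengths[2], lengths[-3]))
        grid = np.exp(-0.5 * ((lengths - mode) / 0.9) ** 2)
        p_norm = grid / grid.sum()
        if unstable[i]:
            shifted = np.exp(-0.5 * ((lengths - (mode - 3)) / 1.8) ** 2)
            p_tum = shifted / shifted.sum()
        else:
            p_tum = p_norm
        n_rows.append(rng.multinomial(reads_per_site, p_norm))
        t_rows.append(rng.multinomial(reads_per_site, p_tum))
        ids.append(f"site{i}")
    tumor = pd.DataFrame(t_rows, columns=cols, index=ids)
    normal = pd.DataFrame(n_rows, columns=cols, index=ids)
    return tumor, normal, [ids[i] for i in range(n_sites) if unstable[i]]


# ---------------------------------------------------------------------------
# structural variants / kataegis planting


def simulate_tandem_dups(n_td: int, seed: int, genome: GenomeModel | None = None,
                         log10_span_mean: float = 4.0,
                         log10_span_sd: float = 0.25,
                         supporting_reads: int = 30) -> pd.DataFrame:
    """Tandem duplications dispersed proportionally to chromosome length,
    spans lognormal around 10 kb (the tandem-duplicator-phenotype regime)."""
    genome = genome or miniature_genome()
    rng = substream(seed, "tandem-dups")
    lens = np.array([l for _, l in genome.chrom_lengths], dtype=float)
    rows = []
    for i in range(n_td):
        ci = rng.choice(len(lens), p=lens / lens.sum())
        span = int(10 ** rng.normal(log10_span_mean, log10_span_sd))
        p1 = int(rng.integers(1, lens[ci] - span))
        rows.append((genome.chroms[ci], p1, "-", genome.chroms[ci],
                     p1 + span, "+", "duplication", supporting_reads, span))
    return pd.DataFrame(rows, columns=["chrom1", "pos1", "strand1", "chrom2",
                                       "pos2", "strand2", "sv_class",
                                       "supporting_reads", "span"])


def plant_kataegis(spec: KataegisSpec, svs: pd.DataFrame, seed: int,
                   genome: GenomeModel | None = None, sample: str = "S1",
                   vaf: float = 0.5, depth: int = DEFAULT_DEPTH
                   ) -> tuple[pd.DataFrame, list[dict]]:
    """APOBEC-type hypermutation clusters near SV breakpoints.

    Cluster mutations are TpC C>T/C>G, share a VAF and a clone label (one
    burst arises in one cell population), and sit within 10 kb of a breakpoint
    of ``svs`` when ``sv_linked`` (otherwise placed uniformly). Returns
    (mutations, truth interval dicts).
    """
    genome = genome or miniature_genome()
    rng = substream(seed, "kataegis")
    apobec_channels = [c for c in CHANNELS_96
                       if c[0] == "T" and c[2] == "C" and c[4] in "GT"]
    rows, intervals = [], []
    for ci in range(spec.n_clusters):
        if spec.sv_linked:
            if svs is None or svs.empty:
                raise ValueError("sv_linked kataegis requires an SV table")
            sv = svs.iloc[int(rng.integers(len(svs)))]
            chrom, anchor = sv["chrom1"], int(sv["pos1"])
            start = max(1, anchor + int(rng.integers(1_000, 10_000)))
        else:
            chrom = genome.chroms[int(rng.integers(len(genome.chroms)))]
            start = int(rng.integers(1, genome.length(chrom) - spec.max_span))
        offsets = np.sort(rng.choice(
            np.arange(spec.max_span), size=spec.cluster_size, replace=False))
        for j, off in enumerate(offsets):
            ch = apobec_channels[int(rng.integers(len(apobec_channels)))]
            ref, alt_base, _, _ = parse_channel(ch)
            d = max(1, int(rng.poisson(depth)))
            a = rng.binomial(d, vaf)
            rows.append((f"{sample}:kat{ci}:{j}", sample, chrom,
                         int(start + off), ref, alt_base, ch, int(a),
                         int(d - a), float(a / d), f"kat{ci}"))
        intervals.append({"sample": sample, "chrom": str(chrom),
                          "start": int(start + offsets[0]),
                          "end": int(start + offsets[-1]),
                          "n_mutations": int(spec.cluster_size)})
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS + ["clone"]), intervals


# ---------------------------------------------------------------------------
# sample QC


def sample_qc(tumor_cell_pct: float | None, purity_estimate: float | None,
              rin: float | None) -> tuple[bool, str | None]:
    """Keep/discard rule for a candidate sample.

    Discard if pathologist tumor-cell content < 50%, genomic purity estimate
    < 20%, or RNA integrity number < 7; boundary values pass. Returns
    (keep, reason-for-discard).
    """
    for name, val in (("tumor_cell_pct", tumor_cell_pct),
                      ("purity_estimate", purity_estimate), ("rin", rin)):
        if val is None:
            raise ValueError(f"missing QC field: {name}")
    if not (0 <= tumor_cell_pct <= 100 and 0 <= purity_estimate <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if tumor_cell_pct < 50:
        return False, "tumor_cell_pct"
    if purity_estimate < 20:
        return False, "purity_estimate"
    if rin < 7:
        return False, "rin"
    return True, None


# ---------------------------------------------------------------------------
# whole-cohort generator


@dataclass
class TumorSim:
    tumor_id: str
    samples: dict            # sample name -> mutation DataFrame
    profiles: dict           # sample name -> SegmentProfile
    signals: dict            # sample name -> BinnedSignal
    svs: dict                # sample name -> BEDPE-like DataFrame
    msi: dict                # sample name -> (tumor table, normal table)
    truth: SyntheticTruth


def simulate_cohort(config: SimConfig, genome: GenomeModel | None = None,
                    bin_size: int = 100_000) -> list[TumorSim]:
    """Generate the full paired-component cohort a `SimConfig` describes."""
    genome = genome or miniature_genome()
    tumors = []
    for t in range(config.n_tumors):
        tumor_id = f"T{t + 1:02d}"
        tseed = int(substream(config.seed, f"tumor:{t}").integers(2 ** 31))
        rng = substream(tseed, "tumor-params")
        lo, hi = config.purity_range
        ploidy = int(rng.choice(config.ploidy_choices))

        a, b, truth = simulate_paired_components(
            config.shared_event_fraction,
            {"n_events": config.mutation_burden,
             "exposures": config.signature_exposures},
            seed=tseed, genome=genome)
        comps = {}
        names = [f"{tumor_id}{chr(ord('a') + i)}"
                 for i in range(config.components_per_tumor)]
        for name, df in zip(names, (a, b)):
            df = df.copy()
            df["sample"] = name
            comps[name] = df

        profiles, sigs, svs, msi = {}, {}, {}, {}
        for k, name in enumerate(names):
            purity = float(rng.uniform(lo, hi))
            prof, sig = simulate_segment_profile(
                ploidy, purity, config.n_lst_events, seed=tseed + k,
                genome=genome, bin_size=bin_size)
            profiles[name], sigs[name] = prof, sig
            truth.purity[name] = purity
            truth.ploidy[name] = ploidy
            truth.segment_profiles[name] = prof.segments.to_dict("records")
            truth.exposures[name] = dict(config.signature_exposures)

            sv = simulate_tandem_dups(config.n_tandem_dups, tseed + k, genome)
            if config.kataegis_spec.n_clusters > 0:
                if sv.empty and config.kataegis_spec.sv_linked:
                    sv = simulate_tandem_dups(config.kataegis_spec.n_clusters,
                                              tseed + 7 + k, genome)
                kat, intervals = plant_kataegis(
                    config.kataegis_spec, sv, tseed + k, genome, sample=name)
                comps[name] = pd.concat([comps[name], kat], ignore_index=True)
                truth.kataegis.extend(intervals)
            svs[name] = sv
            truth.tandem_dups.extend(
                dict(r, sample=name) for r in sv.to_dict("records"))
            if config.msi_spec.n_sites > 0:
                tum, norm, unstable = simulate_msi_profile(
                    config.msi_spec.n_sites, config.msi_spec.unstable_fraction,
                    seed=tseed + k)
                msi[name] = (tum, norm)
                truth.unstable_sites.extend(f"{name}:{s}" for s in unstable)
        tumors.append(TumorSim(tumor_id, comps, profiles, sigs, svs, msi, truth))
    return tumors
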
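"""Synthetic tumor cohorts with known clonal structure, gain times, clock
rates, signature dynamics, driver orderings and expression.

The generator realizes the same generative assumptions the inference stages
invert: mutations accrue at a constant per-copy rate in molecular time,
alt reads are binomial at the locus-specific expected VAF, clock-like
CpG>TpG mutations accumulate linearly with chronological age (accelerated
by a factor ``accel`` after the MRCA), and mutations predating a simulated
gain carry the duplicated multiplicity.  Mutations are only emitted when
they would be callable, i.e. supported by at least ``min_alt_reads`` reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AttributionTable,
    Cohort,
    CNSegment,
    GROUPS,
    Mutation,
    SampleData,
    SampleProfile,
    assign_segments,
)

# Approximate autosome lengths (bp), adequate for length-weighted averages.
CHROM_LENGTHS: dict[str, int] = {
    "chr1": 248_000_000, "chr2": 242_000_000, "chr3": 198_000_000,
    "chr4": 190_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 145_000_000, "chr9": 138_000_000,
    "chr10": 134_000_000, "chr11": 135_000_000, "chr12": 133_000_000,
    "chr13": 114_000_000, "chr14": 107_000_000, "chr15": 102_000_000,
    "chr16": 90_000_000, "chr17": 83_000_000, "chr18": 80_000_000,
    "chr19": 59_000_000, "chr20": 64_000_000, "chr21": 47_000_000,
    "chr22": 51_000_000,
}

BASES = "ACGT"

# Non-clock SNV contexts used for passenger mutations, one per simulated
# signature.  None is C>T at CpG.
_SIGNATURE_CONTEXTS: dict[str, str] = {
    "SBS4": "C[C>A]A",
    "SBS40": "A[T>C]T",
    "SBS2": "T[C>T]T",
    "SBS5": "G[T>G]C",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated cohort.

    ``clone_ccfs`` lists cancer cell fractions of the truncal clone (must be
    1.0) and 0-2 subclones in strictly decreasing order.
    ``subclone_fractions`` gives the share of passenger SNVs carried by each
    subclone.  ``mu_true`` is the clock-mutation rate in CpG>TpG mutations
    per year per diploid genome; after the MRCA it is multiplied by
    ``accel``.  ``pi_true`` is the molecular time of simulated gains within
    the clonal period.  Variants supported by fewer than ``min_alt_reads``
    reads are never emitted, mirroring caller detection limits.
    """

    n_samples: int = 50
    seed: int = 0
    depth: float = 80.0
    purity_range: tuple[float, float] = (0.4, 0.9)
    clone_ccfs: tuple[float, ...] = (1.0, 0.4)
    subclone_fractions: tuple[float, ...] = (0.3,)
    n_snvs: int = 3000
    wgd_prob: float = 0.3
    chrom_gain_prob: float = 0.1
    pi_true: float = 0.3
    mu_true: float = 5.0
    accel: float = 1.0
    age_range: tuple[float, float] = (55.0, 75.0)
    latency_range: tuple[float, float] = (8.0, 22.0)
    min_alt_reads: int = 3
    signature_activity: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"SBS4": (0.5, 0.25), "SBS40": (0.5, 0.75)}
    )
    driver_genes: tuple[str, ...] = ("EGFR", "TP53", "KRAS")
    driver_prob: float = 0.5
    order_noise: float = 0.0
    group_probs: tuple[float, ...] = (0.35, 0.35, 0.2, 0.1)

    def __post_init__(self) -> None:
        ccfs = self.clone_ccfs
        if not ccfs or ccfs[0] != 1.0:
            raise ValueError("first clone CCF must be 1.0")
        if any(b >= a for a, b in zip(ccfs, ccfs[1:])):
            raise ValueError("clone CCFs must be strictly decreasing")
        if len(self.subclone_fractions) != len(ccfs) - 1:
            raise ValueError("need one subclone_fraction per subclone")
        if sum(self.subclone_fractions) >= 1.0:
            raise ValueError("subclone fractions must sum below 1")
        if not (0.0 <= self.pi_true <= 1.0):
            raise ValueError("pi_true must be in [0,1]")
        if self.mu_true <= 0:
            raise ValueError("mu_true must be > 0")
        if self.accel <= 0:
            raise ValueError("accel must be > 0")


@dataclass
class GroundTruth:
    """Per-sample and per-mutation generative truth for a simulated cohort."""

    per_sample: pd.DataFrame      # mrca_age, latency, wgd, pi_true, psi_bar...
    per_mutation: pd.DataFrame    # m_true, ccf_true, clone, signature, ...
    gene_order: tuple[str, ...]   # configured driver order, earliest first


def _sample_rng(config: SimConfig, index: int) -> np.random.Generator:
    # one derived stream per sample: cohorts extend without reshuffling
    return np.random.default_rng([config.seed, index])


def _draw_group(rng: np.random.Generator, probs: Sequence[float]) -> tuple[str, str]:
    g = GROUPS[rng.choice(len(GROUPS), p=np.asarray(probs) / np.sum(probs))]
    smoking = {"AS_N": "never", "EU_N": "never", "EU_S": "smoker"}.get(g, "unknown")
    return g, smoking


def _make_segments(config: SimConfig, rng: np.random.Generator) -> tuple[list[CNSegment], bool]:
    wgd = bool(rng.random() < config.wgd_prob)
    segments = []
    for chrom, length in CHROM_LENGTHS.items():
        if wgd:
            major, minor = 2, 2
        elif rng.random() < config.chrom_gain_prob:
            major, minor = 2, 1
        else:
            major, minor = 1, 1
        segments.append(CNSegment(chrom, 0, length, major, minor, 1.0))
    return segments, wgd


def _segment_weights(segments: Sequence[CNSegment]) -> np.ndarray:
    w = np.array([s.length * max(s.total_cn, 1) for s in segments], float)
    return w / w.sum()


def _snv_from_context(context: str) -> tuple[str, str]:
    change = context.split("[")[1].split("]")[0]
    ref, alt = change.split(">")
    return ref, alt


def _clock_context(rng: np.random.Generator) -> str:
    return f"{BASES[rng.integers(4)]}[C>T]G"


@dataclass
class _PlannedMutation:
    seg_idx: int
    m_true: int
    ccf_true: float
    clone: int          # 0 = truncal
    signature: str
    is_clock: bool
    pre_gain: bool
    gene: Optional[str] = None
    is_driver: bool = False


def _plan_clonal_counts(
    segments: Sequence[CNSegment], diploid_total: float, pi: float,
    rng: np.random.Generator,
) -> list[tuple[int, int, bool, int]]:
    """Poisson counts of clonal mutations per (segment, multiplicity).

    ``diploid_total`` is the expected genome-wide count had the genome stayed
    diploid; gained segments accrue proportionally more after the gain and
    duplicated pre-gain mutations appear once at multiplicity 2.
    Returns (seg_idx, multiplicity, pre_gain, count).
    """
    total_len = sum(s.length for s in segments)
    lam_copy = diploid_total / (2.0 * total_len)   # per copy per bp
    out = []
    for i, seg in enumerate(segments):
        n_orig = 2 if seg.minor_cn > 0 or seg.major_cn == 1 else 1
        state = (seg.major_cn, seg.minor_cn)
        if seg.major_cn >= 2:    # gained at molecular time pi
            n_dup = {(2, 2): 2, (2, 1): 1, (2, 0): 1}.get(state, 1)
            n_single_pre = n_orig - n_dup if state != (2, 0) else 0
            out.append((i, 2, True,
                        rng.poisson(lam_copy * seg.length * pi * n_dup)))
            if n_single_pre:
                out.append((i, 1, True,
                            rng.poisson(lam_copy * seg.length * pi * n_single_pre)))
            out.append((i, 1, False,
                        rng.poisson(lam_copy * seg.length * (1 - pi) * seg.total_cn)))
        else:
            out.append((i, 1, False,
                        rng.poisson(lam_copy * seg.length * 2)))
    return out


def _simulate_sample(config: SimConfig, index: int):
    rng = _sample_rng(config, index)
    sid = f"S{index:04d}"
    purity = float(rng.uniform(*config.purity_range))
    age = float(rng.uniform(*config.age_range))
    latency = float(rng.uniform(*config.latency_range))
    latency = min(latency, age)
    mrca_age = age - latency
    sex = "F" if rng.random() < 0.5 else "M"
    group, smoking = _draw_group(rng, config.group_probs)
    segments, wgd = _make_segments(config, rng)
    psi_bar = (
        sum(s.length * s.total_cn for s in segments)
        / sum(s.length for s in segments)
    )

    sub_ccfs = config.clone_ccfs[1:]
    sub_fracs = config.subclone_fractions
    clonal_share = 1.0 - sum(sub_fracs)
    planned: list[_PlannedMutation] = []

    # --- clonal passengers (non-clock), per-copy constant molecular rate
    sig_names = list(config.signature_activity)
    p_clonal = np.array([config.signature_activity[s][0] for s in sig_names])
    p_clonal = p_clonal / p_clonal.sum()
    p_sub = np.array([config.signature_activity[s][1] for s in sig_names])
    p_sub = p_sub / p_sub.sum()
    for seg_idx, m, pre, count in _plan_clonal_counts(
        segments, config.n_snvs * clonal_share, config.pi_true, rng
    ):
        for sig_i in rng.choice(len(sig_names), p=p_clonal, size=count):
            planned.append(_PlannedMutation(
                seg_idx, m, 1.0, 0, sig_names[sig_i], False, pre))

    # --- clonal clock mutations: mu_true per year per diploid genome
    for seg_idx, m, pre, count in _plan_clonal_counts(
        segments, config.mu_true * mrca_age, config.pi_true, rng
    ):
        for _ in range(count):
            planned.append(_PlannedMutation(
                seg_idx, m, 1.0, 0, "SBS1", True, pre))

    # --- subclonal mutations (multiplicity 1, CCF of their clone)
    seg_w = _segment_weights(segments)
    for j, (ccf, frac) in enumerate(zip(sub_ccfs, sub_fracs), start=1):
        n_pass = rng.poisson(config.n_snvs * frac * psi_bar / 2.0)
        for sig_i in rng.choice(len(sig_names), p=p_sub, size=n_pass):
            seg_idx = int(rng.choice(len(segments), p=seg_w))
            planned.append(_PlannedMutation(
                seg_idx, 1, ccf, j, sig_names[sig_i], False, False))
        # Post-MRCA clock mutations: scaling by 1/CCF keeps the CCF-weighted
        # count an unbiased estimate of accel * mu * latency (later lineages
        # are more numerous but each mutation reaches fewer cells).
        time_share = 1.0 / len(sub_ccfs)
        n_clock = rng.poisson(
            config.accel * config.mu_true * latency * (psi_bar / 2.0)
            * time_share / ccf
        )
        for _ in range(n_clock):
            seg_idx = int(rng.choice(len(segments), p=seg_w))
            planned.append(_PlannedMutation(
                seg_idx, 1, ccf, j, "SBS1", True, False))

    # --- driver mutations, CCFs consistent with the configured gene order
    clone_idx = 0
    for gi, gene in enumerate(config.driver_genes):
        if rng.random() >= config.driver_prob:
            continue
        if config.order_noise > 0 and rng.random() < config.order_noise:
            assigned = int(rng.integers(len(config.clone_ccfs)))
        else:
            assigned = clone_idx
            if rng.random() < 0.5 and clone_idx < len(config.clone_ccfs) - 1:
                clone_idx += 1
        seg_idx = int(rng.choice(len(segments), p=seg_w))
        planned.append(_PlannedMutation(
            seg_idx, 1, config.clone_ccfs[assigned], assigned, "SBS5",
            False, False, gene=gene, is_driver=True))

    # --- read sampling
    mutations: list[Mutation] = []
    truth_rows = []
    used_pos: set[tuple[str, int]] = set()
    mean_denom = purity * psi_bar + 2.0 * (1.0 - purity)
    for pm in planned:
        seg = segments[pm.seg_idx]
        denom = purity * seg.total_cn + 2.0 * (1.0 - purity)
        locus_depth = config.depth * denom / mean_denom
        total = int(rng.poisson(locus_depth))
        if total == 0:
            continue
        p = pm.m_true * purity * pm.ccf_true / denom
        alt = int(rng.binomial(total, min(p, 1.0)))
        if alt < config.min_alt_reads:
            continue
        pos = int(rng.integers(0, seg.length))
        while (seg.chrom, pos) in used_pos:
            pos = int(rng.integers(0, seg.length))
        used_pos.add((seg.chrom, pos))
        if pm.is_clock:
            context = _clock_context(rng)
        else:
            context = _SIGNATURE_CONTEXTS.get(pm.signature, "C[C>A]A")
        ref, alt_base = _snv_from_context(context)
        mut = Mutation(
            chrom=seg.chrom, pos=pos, ref=ref, alt=alt_base,
            alt_reads=alt, total_reads=total, context=context,
            gene=pm.gene, is_driver=pm.is_driver, is_clock=pm.is_clock,
        )
        mutations.append(mut)
        truth_rows.append({
            "sample_id": sid, "key": mut.key, "m_true": pm.m_true,
            "ccf_true": pm.ccf_true, "clone": pm.clone,
            "signature": pm.signature, "is_clock": pm.is_clock,
            "pre_gain": pm.pre_gain, "gene": pm.gene or "",
        })

    profile = SampleProfile(
        sample_id=sid, purity=purity, ploidy=psi_bar, mean_depth=config.depth,
        age_dx=age, sex=sex, group=group, smoking=smoking,
    )
    data = SampleData(
        profile=profile, mutations=mutations, segments=segments,
        seg_index=assign_segments(mutations, segments),
    )
    sample_row = {
        "sample_id": sid, "age_dx": age, "mrca_age": mrca_age,
        "latency": latency, "wgd": wgd, "pi_true": config.pi_true,
        "psi_bar": psi_bar, "purity": purity, "group": group,
    }
    return data, sample_row, truth_rows


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate ``config.n_samples`` tumors with full generative truth.

    The same seed reproduces the identical cohort; each sample draws from a
    stream derived from (seed, sample index).
    """
    samples: dict[str, SampleData] = {}
    sample_rows, mutation_rows = [], []
    for i in range(config.n_samples):
        data, srow, mrows = _simulate_sample(config, i)
        samples[data.profile.sample_id] = data
        sample_rows.append(srow)
        mutation_rows.extend(mrows)
    truth = GroundTruth(
        per_sample=pd.DataFrame(sample_rows).set_index("sample_id"),
        per_mutation=pd.DataFrame(mutation_rows),
        gene_order=config.driver_genes,
    )
    return Cohort(samples), truth


def attribution_from_truth(truth: GroundTruth) -> AttributionTable:
    """Hard per-mutation signature attributions implied by the truth."""
    pm = truth.per_mutation
    probs = pd.get_dummies(pm["signature"]).astype(float)
    probs.index = pd.MultiIndex.from_frame(pm[["sample_id", "key"]])
    return AttributionTable(probs)


# ---------------------------------------------------------------------------
# Indels


@dataclass(frozen=True)
class SimulatedIndel:
    """A VCF-style indel (anchored ref/alt) with its flanking sequence and
    the generating ID-83 channel name."""

    ref: str
    alt: str
    left_flank: str
    right_flank: str
    channel: str


def _rand_seq(rng: np.random.Generator, n: int, exclude: str = "") -> str:
    pool = [b for b in BASES if b not in exclude]
    return "".join(pool[i] for i in rng.integers(len(pool), size=n))


def _other_base(rng: np.random.Generator, base: str) -> str:
    pool = [b for b in BASES if b != base]
    return pool[rng.integers(len(pool))]


def _make_1bp(rng, kind: str, base: str, cls: str) -> SimulatedIndel:
    if cls.endswith("+"):
        lo = int(cls[:-1])
        run = int(rng.integers(lo, lo + 4))
    else:
        run = int(cls)
    anchor = _other_base(rng, base)
    if kind == "Del":
        if run < 1:
            raise ValueError("1bp deletion homopolymer class starts at 1")
        left = _rand_seq(rng, 9, exclude=base) + anchor
        right = base * (run - 1) + _other_base(rng, base) + _rand_seq(rng, 9)
        return SimulatedIndel(anchor + base, anchor, left, right[:10],
                              f"Del:{base}:{cls}")
    left = _rand_seq(rng, 9, exclude=base) + anchor
    right = base * run + _other_base(rng, base) + _rand_seq(rng, 9)
    return SimulatedIndel(anchor, anchor + base, left, right[:10],
                          f"Ins:{base}:{cls}")


_REP_MOTIFS = {2: "AC", 3: "ACG", 4: "ACGT", 5: "ACGTC"}


def _make_rep(rng, kind: str, length: int, cls: str) -> SimulatedIndel:
    motif = _REP_MOTIFS[min(length, 5)]
    if cls.endswith("+"):
        lo = int(cls[:-1])
        units = int(rng.integers(lo, lo + 3))
    else:
        units = int(cls)
    anchor = "T"
    if kind == "Del":
        extra = units - 1          # copies that remain after deletion
    else:
        extra = units              # existing copies next to the insertion
    # flank long enough to hold every tandem copy — no truncation
    right = motif * extra + "TT" + _rand_seq(rng, 6, exclude=motif[0])
    left = _rand_seq(rng, 7, exclude=motif[-1]) + "TT" + anchor
    left = left[-10:]
    label = f"{min(length, 5)}{'+' if length >= 5 else ''}"
    if kind == "Del":
        return SimulatedIndel(anchor + motif, anchor, left, right,
                              f"Del:rep:{label}:{cls}")
    return SimulatedIndel(anchor, anchor + motif, left, right,
                          f"Ins:rep:{label}:{cls}")


def _make_mh(rng, length: int, mh: int) -> SimulatedIndel:
    motif = _REP_MOTIFS[min(length, 5)]
    anchor = "T"
    # right flank begins with the first mh bases of the deleted sequence, then
    # a base that extends neither the homology nor a full repeat copy
    stop = _other_base(rng, motif[mh % length])
    right = motif[:mh] + stop + _rand_seq(rng, 8)
    left = _rand_seq(rng, 7, exclude=motif[-1]) + "TT" + anchor
    label_len = f"{min(length,5)}{'+' if length >= 5 else ''}"
    label_mh = f"{min(mh,5)}{'+' if mh >= 5 else ''}"
    return SimulatedIndel(anchor + motif, anchor, left[-10:], right[:12],
                          f"Del:mh:{label_len}:{label_mh}")


def simulate_indels(
    channel_mix: Mapping[str, float], n: int, seed: int = 0
) -> list[SimulatedIndel]:
    """Draw ``n`` indels from a mixture over ID-83 channel names.

    Each indel is embedded in a flanking sequence constructed so that its
    homopolymer/repeat context matches the requested channel exactly, e.g. a
    1-bp T deletion in the terminal class sits in a run of >= 6 Ts.
    """
    names = list(channel_mix)
    probs = np.array([channel_mix[c] for c in names], float)
    if probs.sum() <= 0:
        raise ValueError("channel mix must have positive total weight")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    out = []
    for idx in rng.choice(len(names), p=probs, size=n):
        parts = names[idx].split(":")
        if parts[1] in ("rep", "mh"):
            kind, sub, length_s, cls = parts
            length = int(length_s.rstrip("+"))
            if sub == "mh":
                out.append(_make_mh(rng, length, int(cls.rstrip("+"))))
            else:
                out.append(_make_rep(rng, kind, length, cls))
        else:
            kind, base, cls = parts
            if base not in "CT":
                raise ValueError(f"unknown channel {names[idx]}")
            out.append(_make_1bp(rng, kind, base, cls))
    return out


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionSim:
    expression: pd.DataFrame      # genes x samples
    hypoxia_genes: list[str]
    hypoxic_samples: list[str]


def simulate_expression(
    n_samples: int = 20,
    n_hypoxia_genes: int = 258,
    n_background_genes: int = 200,
    effect_size: float = 3.0,
    hypoxic_fraction: float = 0.5,
    seed: int = 0,
) -> ExpressionSim:
    """Expression matrix with a hypoxia-responsive gene block.

    Designated hypoxic samples have the scored genes shifted upward by
    ``effect_size`` standard deviations relative to the rest of the cohort.
    """
    if n_hypoxia_genes < 1:
        raise ValueError("need at least one hypoxia gene")
    rng = np.random.default_rng(seed)
    hyp_genes = [f"HYP{i:04d}" for i in range(n_hypoxia_genes)]
    bg_genes = [f"BG{i:04d}" for i in range(n_background_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    values = rng.normal(0.0, 1.0, size=(n_hypoxia_genes + n_background_genes, n_samples))
    n_hypoxic = int(round(hypoxic_fraction * n_samples))
    hypoxic = samples[:n_hypoxic]
    values[:n_hypoxia_genes, :n_hypoxic] += effect_size
    expr = pd.DataFrame(values, index=hyp_genes + bg_genes, columns=samples)
    return ExpressionSim(expr, hyp_genes, hypoxic)
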
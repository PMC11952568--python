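"""Clonal architecture: power gating, WGD calls, multiplicity/CCF estimation,
CCF cluster detection and molecular timing of copy-number gains.

The model throughout: a mutation present at multiplicity ``m`` in a fraction
``CCF`` of tumor cells, in a segment with total tumor copy number ``n_tot``
and sample purity ``rho``, is expected at variant allele fraction

    E[VAF] = m * rho * CCF / (rho * n_tot + 2 * (1 - rho))

with alt reads binomially sampled at the observed locus depth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core_io import AUTOSOMES, CNSegment, Mutation, SampleData, SampleProfile

CCF_CAP = 1.2
CLONALITY_CLASSES = ("early_clonal", "late_clonal", "clonal_unspecified", "subclonal")

# Canonical gained states whose gain time is identifiable from the balance of
# duplicated (m=2) versus single-copy (m=1) clonal mutations.
TIMEABLE_STATES = {(2, 1), (2, 2), (2, 0)}


# ---------------------------------------------------------------------------
# Power gating and WGD


def compute_nrpcc(sample: SampleProfile) -> float:
    """Number of reads per tumor chromosomal copy.

    NRPCC = d * rho / (rho * psi + 2 * (1 - rho)): the mean depth attributable
    to a single copy of the tumor genome, the quantity that governs subclone
    detection power.
    """
    rho, psi, d = sample.purity, sample.ploidy, sample.mean_depth
    if psi <= 0:
        raise ValueError("ploidy must be positive")
    return d * rho / (rho * psi + 2.0 * (1.0 - rho))


def is_eligible(sample: SampleProfile, nrpcc_min: float = 10.0,
                purity_min: float = 0.3) -> bool:
    """Evolution-analysis gate: NRPCC > 10 and purity > 0.3."""
    return compute_nrpcc(sample) > nrpcc_min and sample.purity > purity_min


def classify_wgd(ploidy: float, loh_fraction: float) -> str:
    """Call whole-genome duplication from ploidy and genome LOH fraction.

    WGD iff psi >= 2.9 - 2 * loh_fraction (boundary inclusive).
    """
    if not (0.0 <= loh_fraction <= 1.0):
        raise ValueError("loh_fraction must be in [0,1]")
    return "WGD" if ploidy >= 2.9 - 2.0 * loh_fraction else "nWGD"


def _autosomal(segments: Sequence[CNSegment]) -> list[CNSegment]:
    return [s for s in segments if s.chrom in AUTOSOMES]


def loh_fraction(segments: Sequence[CNSegment]) -> float:
    """Length fraction of the autosomal genome with minor copy number 0."""
    segs = _autosomal(segments)
    total = sum(s.length for s in segs)
    if total == 0:
        return 0.0
    return sum(s.length for s in segs if s.minor_cn == 0) / total


def mcn2_fraction(segments: Sequence[CNSegment]) -> float:
    """Length fraction of the autosomal genome with major copy number >= 2."""
    segs = _autosomal(segments)
    total = sum(s.length for s in segs)
    if total == 0:
        return 0.0
    return sum(s.length for s in segs if s.major_cn >= 2) / total


def mean_autosomal_cn(segments: Sequence[CNSegment]) -> float:
    """Length-weighted mean total copy number over autosomes; subclonal
    segments contribute their clonal-fraction-weighted mixture with diploid."""
    segs = _autosomal(segments)
    total = sum(s.length for s in segs)
    if total == 0:
        raise ValueError("no autosomal segments")
    acc = sum(
        s.length * (s.clonal_fraction * s.total_cn + (1 - s.clonal_fraction) * 2.0)
        for s in segs
    )
    return acc / total


# ---------------------------------------------------------------------------
# Multiplicity


def vaf_denominator(purity: float, n_tot: int) -> float:
    return purity * n_tot + 2.0 * (1.0 - purity)


def expected_vaf(m: float, purity: float, ccf: float, n_tot: int) -> float:
    return m * purity * ccf / vaf_denominator(purity, n_tot)


def estimate_multiplicity(
    mutation: Mutation,
    segment: CNSegment,
    purity: float,
    ccf_candidates: Sequence[float] = (1.0,),
) -> tuple[float, int]:
    """Raw (continuous) multiplicity and the best integer copy state.

    m_raw = VAF * (rho * n_tot + 2 (1 - rho)) / rho.  The integer state is the
    (m, CCF) candidate over m in 1..major_cn and the supplied CCF cluster
    locations maximizing the binomial likelihood of the alt read count.
    """
    if segment.total_cn == 0:
        raise ValueError("segment with total copy number 0 cannot host a mutation")
    if mutation.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rho = purity
    denom = vaf_denominator(rho, segment.total_cn)
    m_raw = mutation.vaf * denom / rho
    a, t = mutation.alt_reads, mutation.total_reads
    best_ll, best_m = -np.inf, 1
    for m in range(1, max(segment.major_cn, 1) + 1):
        for ccf in ccf_candidates:
            p = np.clip(expected_vaf(m, rho, ccf, segment.total_cn), 1e-9, 1 - 1e-9)
            ll = a * np.log(p) + (t - a) * np.log1p(-p)
            if ll > best_ll:
                best_ll, best_m = ll, m
    return m_raw, best_m


# ---------------------------------------------------------------------------
# CCF mixture model


@dataclass
class ClusterSet:
    """1-D binomial-mixture solution over CCF locations.

    The clonal cluster is the one nearest CCF 1.0 (not necessarily the
    largest).
    """

    locations: np.ndarray   # cluster CCFs, in (0, CCF_CAP]
    weights: np.ndarray     # mixing weights, sum to 1
    loglik: float
    bic: float
    n: int

    @property
    def k(self) -> int:
        return len(self.locations)

    @property
    def clonal_index(self) -> int:
        return int(np.argmin(np.abs(self.locations - 1.0)))

    @property
    def clonal_ccf(self) -> float:
        return float(self.locations[self.clonal_index])

    def has_subclone(self, max_ccf: float = 0.8, min_weight: float = 0.02) -> bool:
        """A detected subclone: a non-clonal cluster at CCF < max_ccf carrying
        at least min_weight of mutations."""
        for i, (c, w) in enumerate(zip(self.locations, self.weights)):
            if i != self.clonal_index and c < max_ccf and w >= min_weight:
                return True
        return False


def _log_binom_coeff(alt: np.ndarray, tot: np.ndarray) -> np.ndarray:
    return gammaln(tot + 1) - gammaln(alt + 1) - gammaln(tot - alt + 1)


def _component_loglik(alt, tot, q, locations) -> np.ndarray:
    """n x k matrix of binomial log-likelihoods (without the constant term)."""
    p = np.clip(q[:, None] * locations[None, :], 1e-9, 1 - 1e-9)
    return alt[:, None] * np.log(p) + (tot - alt)[:, None] * np.log1p(-p)


def _mstep_location(alt, tot, q, resp_k, c0: float) -> float:
    """Solve the weighted binomial score equation for one cluster location.

    The score g(c) = sum r (a/c - (t-a) q / (1-qc)) is strictly decreasing, so
    safeguarded Newton from a moment-based start converges to the unique root.
    """
    lo, hi = 1e-4, CCF_CAP
    denom = np.sum(resp_k * tot * q)
    if denom <= 0:
        return c0
    c = float(np.clip(np.sum(resp_k * alt) / denom, lo, hi))
    for _ in range(8):
        qc = np.clip(q * c, None, 1 - 1e-9)
        g = np.sum(resp_k * (alt / c - (tot - alt) * q / (1 - qc)))
        gp = -np.sum(resp_k * (alt / c**2 + (tot - alt) * (q / (1 - qc)) ** 2))
        if gp == 0:
            break
        step = g / gp
        c_new = float(np.clip(c - step, lo, hi))
        if abs(c_new - c) < 1e-8:
            c = c_new
            break
        c = c_new
    return c


def fit_ccf_mixture(
    alt: np.ndarray,
    tot: np.ndarray,
    q: np.ndarray,
    k: int,
    max_iter: int = 150,
    tol: float = 1e-4,
    init_locations: Optional[np.ndarray] = None,
) -> ClusterSet:
    """EM fit of a k-component binomial mixture over CCF locations.

    ``q`` is the per-mutation VAF coefficient m * rho / (rho n_tot + 2(1-rho)),
    so component expected VAFs are q * c_k.
    """
    alt = np.asarray(alt, float)
    tot = np.asarray(tot, float)
    q = np.asarray(q, float)
    n = len(alt)
    const = _log_binom_coeff(alt, tot).sum()
    if init_locations is None:
        raw = np.clip(alt / np.maximum(tot, 1) / np.maximum(q, 1e-9), 1e-3, CCF_CAP)
        qs = np.linspace(0, 1, k + 2)[1:-1]
        locations = np.quantile(raw, qs)
        locations = np.clip(locations, 1e-3, CCF_CAP)
    else:
        locations = np.asarray(init_locations, float).copy()
    weights = np.full(k, 1.0 / k)
    loglik = -np.inf
    for _ in range(max_iter):
        comp = _component_loglik(alt, tot, q, locations) + np.log(weights)[None, :]
        norm = logsumexp(comp, axis=1)
        new_loglik = norm.sum() + const
        resp = np.exp(comp - norm[:, None])
        weights = resp.mean(axis=0)
        weights = np.maximum(weights, 1e-12)
        weights /= weights.sum()
        for j in range(k):
            locations[j] = _mstep_location(alt, tot, q, resp[:, j], locations[j])
        if new_loglik - loglik < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    n_params = 2 * k - 1
    bic = -2.0 * loglik + n_params * np.log(n)
    order = np.argsort(-locations)
    return ClusterSet(locations[order], weights[order], float(loglik), float(bic), n)


def cluster_responsibilities(alt, tot, q, clusters: ClusterSet) -> np.ndarray:
    comp = _component_loglik(
        np.asarray(alt, float), np.asarray(tot, float), np.asarray(q, float),
        clusters.locations,
    ) + np.log(clusters.weights)[None, :]
    return np.exp(comp - logsumexp(comp, axis=1)[:, None])


def detect_clusters(
    alt: np.ndarray,
    tot: np.ndarray,
    q: np.ndarray,
    k_max: int = 4,
    min_mutations: int = 50,
    seed: int = 0,
) -> ClusterSet:
    """Select the CCF cluster count 1..k_max by BIC (ties toward fewer).

    Below ``min_mutations`` a single-cluster fallback is returned with a
    warning.  Each k > 1 adds one random restart on top of the deterministic
    quantile initialization.
    """
    alt = np.asarray(alt, float)
    tot = np.asarray(tot, float)
    q = np.asarray(q, float)
    if len(alt) < min_mutations:
        warnings.warn(
            f"only {len(alt)} mutations (< {min_mutations}); single-cluster fallback"
        )
        return fit_ccf_mixture(alt, tot, q, 1)
    rng = np.random.default_rng(seed)
    best: Optional[ClusterSet] = None
    for k in range(1, k_max + 1):
        fits = [fit_ccf_mixture(alt, tot, q, k)]
        if k > 1:
            init = np.sort(rng.uniform(0.05, CCF_CAP, size=k))
            fits.append(fit_ccf_mixture(alt, tot, q, k, init_locations=init))
        fit = min(fits, key=lambda f: f.bic)
        if best is None or fit.bic < best.bic - 1e-9:
            best = fit
    return best


# ---------------------------------------------------------------------------
# Clonality classes


@dataclass
class TimedMutation:
    """A mutation with its inferred copy state and clonality class."""

    mutation: Mutation
    seg_index: Optional[int]
    m_raw: float
    multiplicity: int
    ccf: float
    cluster: int
    clonality: str
    assignment_probs: dict[str, float]


def assign_clonality(
    multiplicity: int, segment: CNSegment, in_clonal_cluster: bool
) -> str:
    """Temporal class of a mutation relative to a clonal copy-number gain.

    Early clonal: before the gain, on all copies (m >= 2).  Late clonal:
    after the gain, on one copy.  Mutations in un-gained segments are clonal
    without further timing; cluster CCF below the clonal cluster is subclonal.
    """
    if not in_clonal_cluster:
        return "subclonal"
    gained = segment.major_cn >= 2 and segment.clonal_fraction == 1.0
    if gained and multiplicity >= 2:
        return "early_clonal"
    if gained and multiplicity == 1:
        return "late_clonal"
    return "clonal_unspecified"


# ---------------------------------------------------------------------------
# Gain timing


@dataclass
class GainTiming:
    """Molecular time of a copy-number gain inferred from mutation
    multiplicities accumulated under a constant rate."""

    seg_index: int
    state: tuple[int, int]
    pi: float
    ci_low: float
    ci_high: float
    n2: int
    n1: int


def _pi_estimate(state: tuple[int, int], n2: float, n1: float) -> float:
    """Closed-form maximum-likelihood gain time.

    With per-copy mutation rate constant in molecular time, a gain at time pi
    leaves E[n2] : E[n1] characteristic of the state; solving gives
    pi = 3 n2 / (n1 + 2 n2) for (2,1) and 2 n2 / (n1 + 2 n2) for (2,2), (2,0).
    """
    if n1 + n2 == 0:
        return 0.0
    if state == (2, 1):
        pi = 3.0 * n2 / (n1 + 2.0 * n2)
    elif state in ((2, 2), (2, 0)):
        pi = 2.0 * n2 / (n1 + 2.0 * n2)
    else:
        raise ValueError(f"state {state} is not timeable")
    return float(np.clip(pi, 0.0, 1.0))


def time_gain(
    seg_index: int,
    state: tuple[int, int],
    n2: int,
    n1: int,
    min_mutations: int = 5,
    n_boot: int = 200,
    seed: int = 0,
) -> Optional[GainTiming]:
    """Time one gained segment from its (m=2, m=1) clonal mutation counts.

    Returns None when the state is not one of (2,1), (2,2), (2,0) or fewer
    than ``min_mutations`` informative mutations are available.  The CI is a
    percentile bootstrap over mutation resampling.
    """
    if state not in TIMEABLE_STATES:
        return None
    n = n2 + n1
    if n < min_mutations:
        return None
    pi = _pi_estimate(state, n2, n1)
    rng = np.random.default_rng(seed)
    n2_star = rng.binomial(n, n2 / n, size=n_boot)
    boots = np.array([_pi_estimate(state, b, n - b) for b in n2_star])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return GainTiming(seg_index, state, pi, float(min(lo, pi)), float(max(hi, pi)), n2, n1)


# ---------------------------------------------------------------------------
# Per-sample pipeline


@dataclass
class SampleTiming:
    timed: list[TimedMutation]
    clusters: ClusterSet
    gains: list[GainTiming]
    untimed: list[tuple[int, str]]   # (seg_index, reason)


def time_sample(
    data: SampleData,
    k_max: int = 4,
    seed: int = 0,
    min_gain_mutations: int = 5,
) -> SampleTiming:
    """Full clonal deconvolution of one tumor.

    Multiplicities are first estimated against a clonal (CCF=1) state, CCF
    clusters are fitted to the resulting read counts, then each mutation is
    re-assigned to its best (multiplicity, cluster) pair and classified as
    early/late clonal, clonal unspecified, or subclonal.  Canonical gained
    segments are timed from their duplicated/unduplicated mutation balance.
    """
    rho = data.profile.purity
    usable: list[tuple[Mutation, int, CNSegment]] = []
    for mut, si in zip(data.mutations, data.seg_index):
        if si is None:
            continue
        seg = data.segments[si]
        if seg.total_cn == 0 or mut.total_reads == 0:
            continue
        usable.append((mut, si, seg))
    if not usable:
        raise ValueError("no mutations assigned to usable segments")

    m_raw = np.empty(len(usable))
    m0 = np.empty(len(usable), dtype=int)
    for i, (mut, _, seg) in enumerate(usable):
        m_raw[i], m0[i] = estimate_multiplicity(mut, seg, rho)
    denom = np.array([vaf_denominator(rho, seg.total_cn) for _, _, seg in usable])
    alt = np.array([mut.alt_reads for mut, _, _ in usable], float)
    tot = np.array([mut.total_reads for mut, _, _ in usable], float)
    q0 = m0 * rho / denom

    clusters = detect_clusters(alt, tot, q0, k_max=k_max, seed=seed)
    clonal_idx = clusters.clonal_index

    # vectorized re-assignment to the best (multiplicity, cluster) candidate
    major = np.array([max(seg.major_cn, 1) for _, _, seg in usable])
    m_vals = np.arange(1, major.max() + 1)
    p_grid = np.clip(
        m_vals[None, :, None] * rho * clusters.locations[None, None, :]
        / denom[:, None, None],
        1e-9, 1 - 1e-9,
    )
    ll = (alt[:, None, None] * np.log(p_grid)
          + (tot - alt)[:, None, None] * np.log1p(-p_grid)
          + np.log(clusters.weights)[None, None, :])
    ll = np.where(m_vals[None, :, None] > major[:, None, None], -np.inf, ll)
    flat = ll.reshape(len(usable), -1).argmax(axis=1)
    m_best = m_vals[flat // clusters.k]
    k_best = flat % clusters.k
    q_best = m_best * rho / denom
    resp = cluster_responsibilities(alt, tot, q_best, clusters)
    p_clonal = resp[:, clonal_idx]

    timed: list[TimedMutation] = []
    for i, (mut, si, seg) in enumerate(usable):
        clonality = assign_clonality(int(m_best[i]), seg, int(k_best[i]) == clonal_idx)
        side_class = assign_clonality(int(m_best[i]), seg, True)
        probs = {side_class: float(p_clonal[i]), "subclonal": 1.0 - float(p_clonal[i])}
        if side_class == "subclonal":
            probs = {"subclonal": 1.0}
        ccf = float(min(m_raw[i] / m_best[i], CCF_CAP))
        timed.append(
            TimedMutation(mut, si, float(m_raw[i]), int(m_best[i]), ccf,
                          int(k_best[i]), clonality, probs)
        )

    gains: list[GainTiming] = []
    untimed: list[tuple[int, str]] = []
    by_seg: dict[int, list[TimedMutation]] = {}
    for tm in timed:
        by_seg.setdefault(tm.seg_index, []).append(tm)
    for si, seg in enumerate(data.segments):
        state = (seg.major_cn, seg.minor_cn)
        if seg.major_cn < 2:
            continue
        if state not in TIMEABLE_STATES:
            untimed.append((si, f"state {state} not timeable"))
            continue
        muts = [tm for tm in by_seg.get(si, [])
                if tm.clonality in ("early_clonal", "late_clonal")]
        n2 = sum(1 for tm in muts if tm.multiplicity >= 2)
        n1 = sum(1 for tm in muts if tm.multiplicity == 1)
        gt = time_gain(si, state, n2, n1,
                       min_mutations=min_gain_mutations, seed=seed + si)
        if gt is None:
            untimed.append((si, f"only {n2 + n1} informative mutations"))
        else:
            gains.append(gt)
    return SampleTiming(timed, clusters, gains, untimed)


# ---------------------------------------------------------------------------
# Driver timing enrichment


def driver_timing_enrichment(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene 2x2 exact test of early-clonal status against a binary label.

    ``records`` needs columns gene, label (bool, e.g. smoker), early (bool).
    Genes where either margin is all-zero are skipped.  Returns odds ratio,
    p and BH-adjusted FDR per gene.
    """
    rows = []
    for gene, sub in records.groupby("gene"):
        lab = sub["label"].astype(bool).to_numpy()
        early = sub["early"].astype(bool).to_numpy()
        table = np.array([
            [int((lab & early).sum()), int((lab & ~early).sum())],
            [int((~lab & early).sum()), int((~lab & ~early).sum())],
        ])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        odds, p = fisher_exact(table)
        rows.append({"gene": gene, "odds_ratio": odds, "p": p,
                     "n": len(sub),
                     "a": table[0, 0], "b": table[0, 1],
                     "c": table[1, 0], "d": table[1, 1]})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
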
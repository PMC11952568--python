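"""Signature dynamics across tumor evolution: clonal-vs-subclonal activity
fold changes, ID-83 indel classification with homopolymer motifs,
replication-timing correlation, and neoantigen propensity per signature.

Fold changes are computed on soft attribution probabilities: the relative
proportion of a compartment's mutations attributed to a signature is the
mean attribution probability over that compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, wilcoxon
from statsmodels.stats.multitest import multipletests

from .core_io import AttributionTable

CLONAL_CLASSES = ("early_clonal", "late_clonal", "clonal_unspecified")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Clonal vs subclonal fold change


@dataclass
class FoldChangeRecord:
    sample_id: str
    signature: str
    p_clonal: float
    p_subclonal: float
    fold_change: float


def clonality_fold_change(
    attributions: AttributionTable,
    clonality: pd.Series,
    clonal_classes: Sequence[str] = CLONAL_CLASSES,
    subclonal_classes: Sequence[str] = ("subclonal",),
    min_clonal_mass: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample signature fold changes between compartments plus a cohort
    summary.

    For each sample and signature s, p_clonal(s) is the summed attribution
    probability over clonal mutations divided by the clonal mutation count
    (p_subclonal analogous) and FC = p_subclonal / p_clonal.  Samples without
    subclonal mutations are excluded entirely; (sample, signature) cells with
    clonal attributed mass below ``min_clonal_mass`` (or p_clonal = 0) are
    excluded for that signature.  The cohort summary reports the median FC,
    IQR, a signed-rank test of log FC against 0 and BH FDR per signature.

    The same operation serves other compartment contrasts (e.g. early vs
    late clonal) through the class arguments.
    """
    probs = attributions.probs
    lab = clonality.reindex(probs.index)
    is_clonal = lab.isin(clonal_classes).to_numpy()
    is_sub = lab.isin(subclonal_classes).to_numpy()
    sample_ids = probs.index.get_level_values(0)
    samples = pd.unique(sample_ids)

    cl_mass = probs[is_clonal].groupby(level=0).sum().reindex(samples, fill_value=0.0)
    su_mass = probs[is_sub].groupby(level=0).sum().reindex(samples, fill_value=0.0)
    cl_n = pd.Series(is_clonal, index=sample_ids).groupby(level=0).sum() \
        .reindex(samples, fill_value=0)
    su_n = pd.Series(is_sub, index=sample_ids).groupby(level=0).sum() \
        .reindex(samples, fill_value=0)

    usable = (cl_n > 0) & (su_n > 0)
    p_cl = cl_mass.div(cl_n.where(cl_n > 0), axis=0)
    p_su = su_mass.div(su_n.where(su_n > 0), axis=0)
    keep = usable.to_numpy()[:, None] & (cl_mass >= min_clonal_mass).to_numpy() \
        & (p_cl > 0).to_numpy()
    fc = p_su / p_cl
    long = pd.DataFrame({
        "p_clonal": p_cl.where(keep).stack(),
        "p_subclonal": p_su.where(keep).stack(),
        "fold_change": fc.where(keep).stack(),
    }).dropna()
    rec_df = long.reset_index()
    rec_df.columns = ["sample_id", "signature", "p_clonal", "p_subclonal",
                      "fold_change"]
    rows = []
    if len(rec_df):
        for sig, sub in rec_df.groupby("signature"):
            fc = sub["fold_change"].to_numpy()
            logfc = np.log(np.maximum(fc, 1e-12))
            if len(fc) >= 5 and np.any(logfc != 0):
                # normal approximation: ties are common in discrete FCs and
                # would otherwise trigger a slow permutation fallback
                _, p = wilcoxon(logfc, method="approx")
            else:
                p = np.nan
            q1, med, q3 = np.percentile(fc, [25, 50, 75])
            rows.append({"signature": sig, "n": len(fc), "median_fc": med,
                         "iqr_low": q1, "iqr_high": q3, "p": p})
    summary = pd.DataFrame(rows)
    if len(summary):
        ok = summary["p"].notna()
        summary["fdr"] = np.nan
        if ok.any():
            summary.loc[ok, "fdr"] = multipletests(
                summary.loc[ok, "p"], method="fdr_bh")[1]
    return rec_df, summary


# ---------------------------------------------------------------------------
# ID-83 classification


@dataclass(frozen=True)
class Id83Channel:
    """One of the 83 indel context channels.

    ``kind`` is Ins or Del; ``subtype`` is T or C for 1-bp events (purine
    events are complemented to the pyrimidine base), 'rep' for longer events
    at tandem repeats and 'mh' for deletions with flanking microhomology.
    ``size_class`` is the indel length label (1, 2, 3, 4, 5+) and
    ``unit_class`` the homopolymer/repeat/microhomology label.
    ``homopolymer_length`` is set for 1-bp events only: the maximal run of
    the indel base at the site (including the deleted base for deletions).
    """

    kind: str
    subtype: str
    size_class: str
    unit_class: str
    homopolymer_length: Optional[int] = None

    @property
    def name(self) -> str:
        if self.subtype in ("T", "C"):
            return f"{self.kind}:{self.subtype}:{self.unit_class}"
        return f"{self.kind}:{self.subtype}:{self.size_class}:{self.unit_class}"


def _run_left(seq: str, base: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != base:
            break
        n += 1
    return n


def _run_right(seq: str, base: str) -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def _adjacent_copies(seq: str, left: str, right: str) -> int:
    """Tandem copies of ``seq`` immediately flanking the event site."""
    k, n = len(seq), 0
    pos = len(left)
    while pos >= k and left[pos - k : pos] == seq:
        n += 1
        pos -= k
    pos = 0
    while pos + k <= len(right) and right[pos : pos + k] == seq:
        n += 1
        pos += k
    return n


def _microhomology(seq: str, left: str, right: str) -> int:
    """Longest partial match of the deleted sequence with either flank."""
    best = 0
    for k in range(len(seq) - 1, 0, -1):
        if right.startswith(seq[:k]) or left.endswith(seq[-k:]):
            best = k
            break
    return best


def _cap(n: int, terminal: int) -> str:
    return f"{terminal}+" if n >= terminal else str(n)


def classify_id83(
    ref: str, alt: str, left_flank: str, right_flank: str
) -> Id83Channel:
    """Classify a VCF-style indel (shared anchor base) into an ID-83 channel.

    1-bp events are typed by the pyrimidine representation of the indel base
    and the length of the homopolymer run at the site: deletions count the
    deleted base plus adjoining identical bases (classes 1..5, 6+);
    insertions count the adjoining run only (classes 0..4, 5+).  Longer
    deletions are classified by tandem repeat units including the deleted
    copy (1..5, 6+) or, absent repeats, by flanking microhomology length;
    longer insertions by adjacent existing copies (0..4, 5+).

    Flanks shorter than the event neighborhood (6 bp) raise ValueError.
    """
    if len(left_flank) < 6 or len(right_flank) < 6:
        raise ValueError("unclassified: context shorter than 6 bp per flank")
    if len(ref) == len(alt):
        raise ValueError("not an indel")
    if len(ref) > len(alt):
        kind, seq = "Del", ref[len(alt):]
        if ref[: len(alt)] != alt:
            raise ValueError("alleles are not left-anchored")
        left = left_flank + alt
        right = right_flank
    else:
        kind, seq = "Ins", alt[len(ref):]
        if alt[: len(ref)] != ref:
            raise ValueError("alleles are not left-anchored")
        left = left_flank + ref
        right = right_flank

    if len(seq) == 1:
        base = seq
        norm = base if base in "CT" else _COMPLEMENT[base]
        run = _run_left(left, base) + _run_right(right, base)
        if kind == "Del":
            run += 1
            return Id83Channel(kind, norm, "1", _cap(run, 6), run)
        return Id83Channel(kind, norm, "1", _cap(run, 5), run)

    size_class = _cap(len(seq), 5)
    copies = _adjacent_copies(seq, left, right)
    if kind == "Ins":
        return Id83Channel(kind, "rep", size_class, _cap(copies, 5))
    if copies >= 1:
        return Id83Channel(kind, "rep", size_class, _cap(copies + 1, 6))
    mh = _microhomology(seq, left, right)
    if mh >= 1:
        return Id83Channel(kind, "mh", size_class, _cap(mh, 5))
    return Id83Channel(kind, "rep", size_class, "1")


def min_homopolymer_by_signature(
    channels: Sequence[Id83Channel],
    attributions: pd.DataFrame,
    prob_threshold: float = 0.5,
) -> dict[str, int]:
    """Per-signature minimum homopolymer length among majority-attributed
    1-bp indels.

    ``attributions`` is aligned row-wise with ``channels`` (one row per
    indel, one column per signature).  Signatures without any indel at
    probability >= ``prob_threshold`` are absent from the result.
    """
    if len(channels) != len(attributions):
        raise ValueError("channels and attributions must align row-wise")
    out: dict[str, int] = {}
    probs = attributions.to_numpy()
    for j, sig in enumerate(attributions.columns):
        lengths = [
            ch.homopolymer_length
            for ch, p in zip(channels, probs[:, j])
            if p >= prob_threshold and ch.homopolymer_length is not None
        ]
        if lengths:
            out[sig] = int(min(lengths))
    return out


# ---------------------------------------------------------------------------
# Replication timing


def replication_timing_correlation(
    deletion_counts: Mapping[str, float] | pd.Series,
    log2_el: Mapping[str, float] | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation between per-chromosome deletion counts and the
    chromosome's median replication timing log2(E/L).

    Requires >= 3 chromosomes present in both inputs; zero variance in
    either vector raises ValueError.
    """
    counts = pd.Series(deletion_counts, dtype=float)
    timing = pd.Series(log2_el, dtype=float)
    common = counts.index.intersection(timing.index)
    if len(common) < 3:
        raise ValueError("need >= 3 chromosomes with both values")
    x = counts.loc[common].to_numpy()
    y = timing.loc[common].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Neoantigen propensity


def neoantigen_propensity(
    attributions: pd.DataFrame,
    neoantigenic: Sequence[bool] | pd.Series,
    min_mass: float = 10.0,
) -> pd.Series:
    """Neoantigens per 1000 attributed mutations, per signature.

    propensity(s) = 1000 * sum_m P(s|m) I(neoantigenic_m) / sum_m P(s|m);
    signatures with total attributed mass below ``min_mass`` are suppressed.
    """
    neo = np.asarray(neoantigenic, bool)
    if len(neo) != len(attributions):
        raise ValueError("flags and attributions must align row-wise")
    probs = attributions.to_numpy()
    mass = probs.sum(axis=0)
    neo_mass = probs[neo].sum(axis=0) if neo.any() else np.zeros(probs.shape[1])
    out = {}
    for j, sig in enumerate(attributions.columns):
        if mass[j] >= min_mass:
            out[sig] = 1000.0 * neo_mass[j] / mass[j]
    return pd.Series(out, name="neoantigens_per_1000")
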
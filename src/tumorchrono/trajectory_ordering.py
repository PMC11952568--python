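"""Driver ordering: pairwise CCF-based precedence, agony-minimizing consensus
ranking over resampled cohorts, and co-occurrence / mutual-exclusivity tests.

A sample is informative for ordering only when it carries a detectable
subclone (a CCF cluster below 0.8), so that CCF differences approximate
temporal order.  Per-sample verdicts are aggregated into a precedence graph
whose minimum-agony ranking — agony(r) = sum over arcs (u,v) of
max(0, r(u) - r(v) + 1) — is the consensus temporal order of driver genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .clonal_architecture import ClusterSet

A_BEFORE_B = "a_before_b"
B_BEFORE_A = "b_before_a"
UNORDERED = "unordered"


# ---------------------------------------------------------------------------
# Pairwise ordering


def _peak_side(ccf: float, clusters: ClusterSet) -> str:
    """'upper' when the CCF sits at or above the clonal peak, else 'lower'.

    A CCF nearest to a subclonal cluster is 'lower' regardless of value.
    """
    idx = int(np.argmin(np.abs(clusters.locations - ccf)))
    if idx != clusters.clonal_index:
        return "lower"
    return "upper" if ccf >= clusters.clonal_ccf else "lower"


def sample_is_informative(clusters: ClusterSet, max_ccf: float = 0.8) -> bool:
    """Ordering eligibility: the tumor has a detectable subclone (CCF < 0.8)."""
    return clusters.has_subclone(max_ccf=max_ccf)


def pairwise_order(
    ccf_a: Optional[float],
    ccf_b: Optional[float],
    clusters: ClusterSet,
    margin: float = 0.2,
) -> Optional[str]:
    """Order two driver mutations within one tumor from their CCFs.

    A precedes B when CCF_A - CCF_B > margin, or when A sits on the upper
    side of the clonal peak while B sits on the lower side or in a subclonal
    cluster; symmetrically for B before A; otherwise unordered.  Returns
    None when either gene is unmutated.
    """
    if ccf_a is None or ccf_b is None:
        return None
    side_a, side_b = _peak_side(ccf_a, clusters), _peak_side(ccf_b, clusters)
    if ccf_a - ccf_b > margin or (side_a == "upper" and side_b == "lower"):
        return A_BEFORE_B
    if ccf_b - ccf_a > margin or (side_b == "upper" and side_a == "lower"):
        return B_BEFORE_A
    return UNORDERED


# ---------------------------------------------------------------------------
# Precedence graph


@dataclass(frozen=True)
class Arc:
    u: str
    v: str
    support: int
    fraction: float


@dataclass
class PrecedenceGraph:
    nodes: tuple[str, ...]
    arcs: tuple[Arc, ...]


Verdict = tuple[str, str, str]   # (gene_a, gene_b, verdict)


def build_precedence(
    verdicts: Iterable[Verdict],
    nodes: Sequence[str],
    min_support: float = 0.2,
) -> PrecedenceGraph:
    """Aggregate per-sample pairwise verdicts into a precedence graph.

    An arc u -> v is kept when u-before-v verdicts outnumber the reverse and
    cover at least ``min_support`` of the informative samples for that pair
    (any non-None verdict counts as informative).
    """
    wins: dict[tuple[str, str], int] = {}
    informative: dict[frozenset, int] = {}
    for a, b, verdict in verdicts:
        if verdict is None:
            continue
        informative[frozenset((a, b))] = informative.get(frozenset((a, b)), 0) + 1
        if verdict == A_BEFORE_B:
            wins[(a, b)] = wins.get((a, b), 0) + 1
        elif verdict == B_BEFORE_A:
            wins[(b, a)] = wins.get((b, a), 0) + 1
    arcs = []
    for (u, v), n_uv in sorted(wins.items()):
        if u == v:
            continue
        n_vu = wins.get((v, u), 0)
        n_inf = informative[frozenset((u, v))]
        frac = n_uv / n_inf
        if n_uv > n_vu and frac >= min_support:
            arcs.append(Arc(u, v, n_uv, frac))
    return PrecedenceGraph(tuple(nodes), tuple(arcs))


# ---------------------------------------------------------------------------
# Agony minimization


@dataclass
class Ranking:
    ranks: dict[str, int]
    agony: int


def agony(ranks: Mapping[str, int], arcs: Iterable[tuple[str, str]]) -> int:
    """Penalty of arcs pointing against the ranking (lower rank = earlier)."""
    return sum(max(0, ranks[u] - ranks[v] + 1) for u, v in arcs)


def _agony_array(rank_matrix: np.ndarray, arc_idx: np.ndarray) -> np.ndarray:
    if len(arc_idx) == 0:
        return np.zeros(rank_matrix.shape[0], dtype=int)
    diffs = rank_matrix[:, arc_idx[:, 0]] - rank_matrix[:, arc_idx[:, 1]] + 1
    return np.maximum(diffs, 0).sum(axis=1)


def _exact_min_agony(nodes: Sequence[str], arcs: Sequence[tuple[str, str]]) -> Ranking:
    """Exhaustive search over rank assignments in 0..n-1 (optimal ranks can
    always be compressed into that range)."""
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    arc_idx = np.array([[idx[u], idx[v]] for u, v in arcs], dtype=int)
    grids = np.meshgrid(*[np.arange(n)] * n, indexing="ij")
    ranks_all = np.stack([g.ravel() for g in grids], axis=1).astype(np.int8)
    scores = _agony_array(ranks_all, arc_idx)
    best = int(np.argmin(scores))
    return Ranking({g: int(ranks_all[best, i]) for i, g in enumerate(nodes)},
                   int(scores[best]))


def _hill_climb(
    nodes: Sequence[str],
    arcs: Sequence[tuple[str, str]],
    rng: np.random.Generator,
    n_restarts: int = 30,
) -> Ranking:
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    arc_idx = np.array([[idx[u], idx[v]] for u, v in arcs], dtype=int)

    def score(r: np.ndarray) -> int:
        return int(_agony_array(r[None, :], arc_idx)[0])

    best_r, best_s = None, None
    for _ in range(n_restarts):
        r = rng.integers(0, n, size=n)
        s = score(r)
        improved = True
        while improved:
            improved = False
            for i in range(n):
                cand = np.tile(r, (n, 1))
                cand[:, i] = np.arange(n)
                sc = _agony_array(cand, arc_idx)
                j = int(np.argmin(sc))
                if sc[j] < s:
                    r, s = cand[j].copy(), int(sc[j])
                    improved = True
        if best_s is None or s < best_s:
            best_r, best_s = r, s
    return Ranking({g: int(best_r[idx[g]]) for g in nodes}, best_s)


def agony_rank(
    graph: PrecedenceGraph,
    seed: int = 0,
    exact_limit: int = 7,
    n_restarts: int = 30,
) -> Ranking:
    """Minimum-agony ranking of a precedence graph.

    Exact (exhaustive) up to ``exact_limit`` nodes; coordinate-descent hill
    climbing with random restarts above.  An empty graph ranks everything 0.
    """
    nodes = graph.nodes
    arcs = [(a.u, a.v) for a in graph.arcs]
    if not arcs:
        return Ranking({g: 0 for g in nodes}, 0)
    if len(nodes) <= exact_limit:
        return _exact_min_agony(nodes, arcs)
    return _hill_climb(nodes, arcs, np.random.default_rng(seed), n_restarts)


# ---------------------------------------------------------------------------
# Resampled consensus


@dataclass
class ConsensusResult:
    ranking: Ranking
    graph: PrecedenceGraph             # consensus arcs (stability >= cutoff)
    arc_stability: pd.DataFrame        # per-arc bootstrap stability fraction


def consensus_ranking(
    sample_verdicts: Mapping[str, Sequence[Verdict]],
    genes: Sequence[str],
    n_resamples: int = 100,
    seed: int = 0,
    min_support: float = 0.2,
    stability_cutoff: float = 0.5,
) -> ConsensusResult:
    """Consensus driver order via bootstrap over samples.

    Samples (patients) are resampled with replacement ``n_resamples`` times;
    each resample yields a precedence graph, and arcs recurring in at least
    ``stability_cutoff`` of resamples form the consensus graph whose
    minimum-agony ranking is returned.
    """
    rng = np.random.default_rng(seed)
    sample_ids = sorted(sample_verdicts)
    counts: dict[tuple[str, str], int] = {}
    for _ in range(n_resamples):
        pick = rng.choice(len(sample_ids), size=len(sample_ids), replace=True)
        verdicts = itertools.chain.from_iterable(
            sample_verdicts[sample_ids[i]] for i in pick)
        g = build_precedence(verdicts, genes, min_support=min_support)
        for arc in g.arcs:
            counts[(arc.u, arc.v)] = counts.get((arc.u, arc.v), 0) + 1
    stability = pd.DataFrame(
        [{"u": u, "v": v, "stability": c / n_resamples}
         for (u, v), c in sorted(counts.items())]
    )
    full = build_precedence(
        itertools.chain.from_iterable(sample_verdicts.values()),
        genes, min_support=min_support)
    support = {(a.u, a.v): a for a in full.arcs}
    arcs = tuple(
        support.get((u, v), Arc(u, v, c, c / n_resamples))
        for (u, v), c in sorted(counts.items())
        if c / n_resamples >= stability_cutoff
    )
    graph = PrecedenceGraph(tuple(genes), arcs)
    return ConsensusResult(agony_rank(graph, seed=seed), graph, stability)


# ---------------------------------------------------------------------------
# Co-occurrence / mutual exclusivity


def cooccurrence(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Fisher tests on a samples x genes binary mutation matrix.

    OR > 1 is labeled co-occurrence, OR < 1 mutual exclusivity; p-values are
    BH-adjusted across pairs.  Pairs with a degenerate margin (a gene mutated
    in all or no samples) are skipped.
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least two genes")
    mat = presence.astype(bool)
    rows = []
    for ga, gb in itertools.combinations(mat.columns, 2):
        a, b = mat[ga].to_numpy(), mat[gb].to_numpy()
        table = np.array([
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        odds, p = fisher_exact(table)
        label = "co_occurrence" if odds > 1 else (
            "mutual_exclusivity" if odds < 1 else "independent")
        rows.append({"gene_a": ga, "gene_b": gb, "odds_ratio": odds,
                     "p": p, "relationship": label,
                     "n11": table[0, 0], "n10": table[0, 1],
                     "n01": table[1, 0], "n00": table[1, 1]})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
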
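"""Simplified tetraploid linkage mapping for duplex x nulliplex markers.

Pairwise recombination fractions are estimated by maximum likelihood under a
fully tetrasomic (random chromosome pairing) two-locus model, matching the
"random pairing" mapping option used for segmental allotetraploids even when
the data are predominantly disomic — which deliberately compresses the map.

The two-locus table is built by exhaustive enumeration. Both loci are duplex
in coupling (the two M-origin chromosomes carry M at both loci). One of the
three bivalent configurations is drawn uniformly: the homogenetic one (M-M,
A-A) contributes constant-origin chromatids, so the gamete is (AM, AM); each
of the two heterogenetic configurations pairs M with A in both bivalents and
each gamete chromatid is M or A at the first locus with probability 1/2 and
switches origin between the loci with probability r.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as hier_average
from scipy.optimize import minimize_scalar
from scipy.sparse.csgraph import shortest_path
from scipy.special import gammaln
from scipy.stats import spearmanr

from .data import MISSING, GameteMatrix, MarkerDef


class LinkageError(ValueError):
    pass


@dataclass
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    r_hat: float
    lod: float  # likelihood-ratio LOD vs r = 0.5 under the two-locus model
    n_informative: int
    lod_independence: float = 0.0  # G^2 independence LOD; robust to model misfit
    degenerate: bool = False


@dataclass
class LinkageGroupMap:
    lg_id: str
    marker_ids: list[str]  # in map order
    positions_cm: list[float]
    length_cm: float


@dataclass
class GeneticMap:
    groups: list[LinkageGroupMap]
    unassigned: list[str]

    @property
    def total_length_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    def to_frame(self, markers: dict[str, MarkerDef] | None = None) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for mid, cm in zip(g.marker_ids, g.positions_cm):
                row = {"lg_id": g.lg_id, "marker_id": mid, "position_cM": cm}
                if markers and mid in markers:
                    row["chromosome"] = markers[mid].chromosome
                    row["position_bp"] = markers[mid].position_bp
                rows.append(row)
        return pd.DataFrame(rows)


def two_locus_probs(r: float) -> np.ndarray:
    """Joint gamete genotype probabilities, 3x3 over M-dose (0,1,2) at each locus."""
    if not 0.0 <= r <= 0.5:
        raise LinkageError(f"recombination fraction {r} outside [0, 0.5]")
    # chromatid pattern (origin at locus1, origin at locus2), 1 = M
    chromatid = {
        (1, 1): (1.0 - r) / 2.0,
        (1, 0): r / 2.0,
        (0, 1): r / 2.0,
        (0, 0): (1.0 - r) / 2.0,
    }
    table = np.zeros((3, 3))
    table[1, 1] += 1.0 / 3.0  # homogenetic configuration: always (AM, AM)
    for (a1, a2), p1 in chromatid.items():
        for (b1, b2), p2 in chromatid.items():
            table[a1 + b1, a2 + b2] += (2.0 / 3.0) * p1 * p2
    return table


def _pair_counts(col_i: np.ndarray, col_j: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over gametes observed at both markers."""
    mask = (col_i != MISSING) & (col_j != MISSING)
    table = np.zeros((3, 3))
    np.add.at(table, (col_i[mask].astype(int), col_j[mask].astype(int)), 1.0)
    return table


def _loglik_r(counts: np.ndarray, r: float) -> float:
    probs = two_locus_probs(r)
    if np.any((counts > 0) & (probs == 0.0)):
        return -math.inf
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, counts * np.log(np.where(probs > 0, probs, 1.0)), 0.0)
    coef = gammaln(counts.sum() + 1) - gammaln(counts + 1).sum()
    return float(coef + logp.sum())


def _independence_lod(counts: np.ndarray) -> float:
    """G-squared test of row/column independence, expressed on the LOD scale.

    Unlinked markers score ~0 here even when the tetrasomic two-locus model
    itself fits the (predominantly disomic) data poorly, which makes this the
    robust grouping score; the likelihood-ratio LOD against r = 0.5 absorbs
    model misfit and can be large for markers on different chromosomes.
    """
    n = counts.sum()
    if n == 0:
        return 0.0
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(counts / np.where(expected > 0, expected, 1.0)), 0.0)
    g2 = 2.0 * terms.sum()
    return float(max(g2, 0.0) / (2.0 * math.log(10.0)))


def estimate_rf(
    joint_counts: np.ndarray, marker_i: str = "", marker_j: str = ""
) -> PairwiseLinkage:
    """ML recombination fraction over [0, 0.5] with LOD against r = 0.5."""
    counts = np.asarray(joint_counts, dtype=float)
    if counts.shape != (3, 3):
        raise LinkageError("joint counts must be 3x3")
    n = int(counts.sum())
    if n < 1:
        raise LinkageError("no informative gamete pairs")
    degenerate = bool((counts > 0).sum() == 1)
    res = minimize_scalar(
        lambda r: -_loglik_r(counts, r),
        bounds=(0.0, 0.5),
        method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = float(res.x)
    ll_hat = _loglik_r(counts, r_hat)
    # the bounded optimiser never evaluates the exact boundary; snap if better
    for boundary in (0.0, 0.5):
        ll_b = _loglik_r(counts, boundary)
        if ll_b >= ll_hat:
            r_hat, ll_hat = boundary, ll_b
    lod = (ll_hat - _loglik_r(counts, 0.5)) / math.log(10.0)
    return PairwiseLinkage(
        marker_i, marker_j, r_hat, max(lod, 0.0), n,
        lod_independence=_independence_lod(counts), degenerate=degenerate,
    )


def pairwise_linkage(g: GameteMatrix) -> list[PairwiseLinkage]:
    """Recombination fraction and LOD for every marker pair."""
    out = []
    for i, j in itertools.combinations(range(g.n_markers), 2):
        counts = _pair_counts(g.genotype[:, i], g.genotype[:, j])
        if counts.sum() < 1:
            raise LinkageError(
                f"zero co-observed gametes for {g.markers[i].marker_id} / "
                f"{g.markers[j].marker_id}"
            )
        out.append(
            estimate_rf(counts, g.markers[i].marker_id, g.markers[j].marker_id)
        )
    return out


def kosambi(r: float) -> float:
    """Kosambi map distance in cM; r must be in [0, 0.5)."""
    if not 0.0 <= r < 0.5:
        raise LinkageError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def group_markers(
    pairwise: list[PairwiseLinkage],
    lod_threshold: float,
    score: str = "lod",
) -> tuple[list[list[str]], list[str]]:
    """Connected components of the LOD graph; singletons are unassigned.

    ``score`` selects the edge weight: "lod" (likelihood-ratio against
    r = 0.5) or "independence" (G-squared independence LOD, the robust
    choice for separating chromosomes when inheritance is mostly disomic).
    """
    if score not in ("lod", "independence"):
        raise LinkageError(f"unknown grouping score {score!r}")
    graph = nx.Graph()
    all_markers: list[str] = []
    for p in pairwise:
        for m in (p.marker_i, p.marker_j):
            if m not in graph:
                graph.add_node(m)
                all_markers.append(m)
        value = p.lod if score == "lod" else p.lod_independence
        if value >= lod_threshold:
            graph.add_edge(p.marker_i, p.marker_j)
    groups, unassigned = [], []
    for comp in nx.connected_components(graph):
        members = [m for m in all_markers if m in comp]
        if len(members) == 1:
            unassigned.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda ms: (-len(ms), ms[0]))
    return groups, unassigned


def linkage_dendrogram(
    marker_ids: list[str], dist: np.ndarray
) -> np.ndarray:
    """Average-linkage dendrogram on map distances, as a cross-check view."""
    from scipy.spatial.distance import squareform

    return hier_average(squareform(dist, checks=False))


def _distance_matrix(
    marker_ids: list[str],
    pairwise: list[PairwiseLinkage],
    r_cap: float = 0.4999,
    k_neighbors: int = 3,
) -> np.ndarray:
    """Geodesic Kosambi distances for ordering.

    Long-range recombination fractions saturate under mixed pairing, so the
    raw distance matrix is far from additive at range. Only each marker's
    ``k_neighbors`` shortest distances are trusted as edges; all other pairs
    are completed by graph shortest path (isomap-style). Pairs left
    unreachable fall back to their direct (capped) distance.
    """
    index = {m: k for k, m in enumerate(marker_ids)}
    n = len(marker_ids)
    direct = np.full((n, n), np.inf)
    np.fill_diagonal(direct, 0.0)
    for p in pairwise:
        if p.marker_i in index and p.marker_j in index:
            i, j = index[p.marker_i], index[p.marker_j]
            direct[i, j] = direct[j, i] = kosambi(min(p.r_hat, r_cap))
    if n <= k_neighbors + 1:
        return direct
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        nn = np.argsort(direct[i], kind="stable")[1 : k_neighbors + 1]
        keep[i, nn] = True
    keep |= keep.T
    # dense csgraph input treats 0 as "no edge"; floor kept edges at epsilon
    d = shortest_path(np.where(keep, np.maximum(direct, 1e-9), 0.0), method="D", directed=False)
    unreachable = np.isinf(d)
    if unreachable.any():
        d[unreachable] = direct[unreachable]
        finite_max = np.nanmax(np.where(np.isinf(d), np.nan, d))
        d = np.where(np.isinf(d), finite_max, d)
    return d


def _classical_mds_1d(d: np.ndarray) -> np.ndarray:
    """First principal coordinate of classical (Torgerson) MDS."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    k = int(np.argmax(vals))
    return vecs[:, k] * math.sqrt(max(vals[k], 0.0))


def _polish_order(order_idx: list[int], d: np.ndarray, max_window: int = 4) -> list[int]:
    """Greedy segment-reversal (2-opt) polish minimising adjacent distance."""

    def cost(seq: list[int]) -> float:
        return float(sum(d[a, b] for a, b in zip(seq[:-1], seq[1:])))

    best = list(order_idx)
    best_cost = cost(best)
    improved = True
    while improved:
        improved = False
        for w in range(2, min(max_window, len(best)) + 1):
            for s in range(len(best) - w + 1):
                trial = best[:s] + best[s : s + w][::-1] + best[s + w :]
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best, best_cost, improved = trial, c, True
    return best


def order_markers(
    marker_ids: list[str],
    pairwise: list[PairwiseLinkage],
    markers: dict[str, MarkerDef] | None = None,
) -> tuple[list[str], list[float]]:
    """Order a linkage group by 1-D classical MDS and place markers in cM.

    The MDS order is polished by greedy segment reversal (2-opt over short
    windows) to undo local flips caused by noisy nearby estimates. Positions
    are the cumulative Kosambi distances of adjacent pairs in the recovered
    order. Orientation: the end whose marker has the smaller bp position
    (when metadata are given) becomes position 0; ties in the MDS coordinate
    are broken by marker id.
    """
    if len(marker_ids) < 2:
        raise LinkageError("need at least two markers to order")
    if len(marker_ids) == 2:
        order = sorted(
            marker_ids,
            key=lambda m: (markers[m].position_bp if markers else 0, m),
        )
        p = next(
            q for q in pairwise
            if {q.marker_i, q.marker_j} == set(marker_ids)
        )
        return order, [0.0, kosambi(min(p.r_hat, 0.4999))]
    d = _distance_matrix(marker_ids, pairwise)
    coord = _classical_mds_1d(d)
    order_idx = sorted(range(len(marker_ids)), key=lambda k: (coord[k], marker_ids[k]))
    order_idx = _polish_order(order_idx, d)
    ordered = [marker_ids[k] for k in order_idx]
    if markers is not None:
        first_bp = markers[ordered[0]].position_bp
        last_bp = markers[ordered[-1]].position_bp
        if last_bp < first_bp:
            ordered = ordered[::-1]
    rhat = {}
    for p in pairwise:
        rhat[(p.marker_i, p.marker_j)] = p.r_hat
        rhat[(p.marker_j, p.marker_i)] = p.r_hat
    index = {m: k for k, m in enumerate(marker_ids)}
    positions = [0.0]
    for a, b in zip(ordered[:-1], ordered[1:]):
        r = rhat.get((a, b))
        step = kosambi(min(r, 0.4999)) if r is not None else d[index[a], index[b]]
        positions.append(positions[-1] + step)
    return ordered, positions


def build_map(
    g: GameteMatrix,
    lod_threshold: float,
    pairwise: list[PairwiseLinkage] | None = None,
    grouping_score: str = "independence",
) -> tuple[GeneticMap, list[PairwiseLinkage]]:
    """Group, order and place all markers; returns the map and pairwise table."""
    if pairwise is None:
        pairwise = pairwise_linkage(g)
    meta = {m.marker_id: m for m in g.markers}
    groups, unassigned = group_markers(pairwise, lod_threshold, score=grouping_score)
    lgs = []
    for k, members in enumerate(groups, start=1):
        sub = [p for p in pairwise if p.marker_i in members and p.marker_j in members]
        ordered, pos = order_markers(members, sub, meta)
        lgs.append(
            LinkageGroupMap(
                lg_id=f"LG{k}",
                marker_ids=ordered,
                positions_cm=pos,
                length_cm=pos[-1],
            )
        )
    return GeneticMap(groups=lgs, unassigned=unassigned), pairwise


def marey_diagnostics(
    gmap: GeneticMap, markers: dict[str, MarkerDef]
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Synteny and colinearity of the genetic map against physical positions.

    Per linkage group: the majority physical chromosome, the fraction of its
    markers on that chromosome, Spearman rho between cM and bp (NA below 3
    markers), and the cM/Mb rate over the physical span of its majority-
    chromosome markers. Overall synteny is the percentage of mapped markers
    lying on their group's majority chromosome. The third return value is
    the per-marker Marey table (lg, marker, cM, chromosome, bp).
    """
    lg_rows, marey_rows = [], []
    n_syntenic = 0
    n_mapped = 0
    for g in gmap.groups:
        chroms = [markers[m].chromosome for m in g.marker_ids]
        majority = max(set(chroms), key=chroms.count)
        on_major = [
            (cm, markers[m].position_bp)
            for m, cm in zip(g.marker_ids, g.positions_cm)
            if markers[m].chromosome == majority
        ]
        n_mapped += len(g.marker_ids)
        n_syntenic += len(on_major)
        cms = [p[0] for p in on_major]
        bps = [p[1] for p in on_major]
        if len(on_major) >= 3 and len(set(cms)) > 1 and len(set(bps)) > 1:
            rho = float(spearmanr(cms, bps)[0])
        else:
            rho = float("nan")
        span_mb = (
            (max(p[1] for p in on_major) - min(p[1] for p in on_major)) / 1e6
            if len(on_major) >= 2
            else float("nan")
        )
        rate = g.length_cm / span_mb if span_mb and span_mb > 0 else float("nan")
        lg_rows.append(
            {
                "lg_id": g.lg_id,
                "n_markers": len(g.marker_ids),
                "majority_chromosome": majority,
                "synteny_pct": 100.0 * len(on_major) / len(g.marker_ids),
                "spearman_rho": rho,
                "length_cM": g.length_cm,
                "span_Mb": span_mb,
                "rate_cM_per_Mb": rate,
            }
        )
        for m, cm in zip(g.marker_ids, g.positions_cm):
            marey_rows.append(
                {
                    "lg_id": g.lg_id,
                    "marker_id": m,
                    "position_cM": cm,
                    "chromosome": markers[m].chromosome,
                    "position_bp": markers[m].position_bp,
                }
            )
    per_lg = pd.DataFrame(lg_rows)
    synteny_pct = 100.0 * n_syntenic / n_mapped if n_mapped else float("nan")
    return per_lg, synteny_pct, pd.DataFrame(marey_rows)
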
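"""Independent oracles used by unit and acceptance tests.

Everything here is deliberately written from first principles (enumeration,
brute-force grids) and never calls the estimator code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def enumerate_single_locus(pp: float, beta: float = 0.0) -> tuple[float, float, float]:
    """(p_AA, p_AM, p_MM) at a duplex AAMM locus by exhaustive enumeration.

    With probability ``pp`` pairing is strictly homologous (gamete AM).
    Otherwise one of the three bivalent configurations of the chromosomes
    {M1, M2, A1, A2} is drawn uniformly; the gamete takes one chromatid from
    each bivalent (uniform over the two parental origins of the bivalent).
    Within the random-pairing fraction, double reduction occurs at relative
    frequency ``beta`` and delivers AA or MM with probability 1/2 each.
    """
    chroms = ["M1", "M2", "A1", "A2"]
    pairings = [
        (("M1", "M2"), ("A1", "A2")),
        (("M1", "A1"), ("M2", "A2")),
        (("M1", "A2"), ("M2", "A1")),
    ]
    probs = np.zeros(3)  # index = M dose of the gamete
    for biv1, biv2 in pairings:
        for c1, c2 in itertools.product(biv1, biv2):
            dose = (c1[0] == "M") + (c2[0] == "M")
            probs[dose] += (1.0 / 3.0) * 0.25
    assert set(chroms) == {"M1", "M2", "A1", "A2"}
    dr = np.array([0.5, 0.0, 0.5])  # DR gametes: AA or MM, 1/2 each
    random_part = (1.0 - beta) * probs + beta * dr
    out = pp * np.array([0.0, 1.0, 0.0]) + (1.0 - pp) * random_part
    return (float(out[0]), float(out[1]), float(out[2]))


def _multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Vectorised multinomial log-likelihood; counts (m,3), probs (g,3) -> (m,g)."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    probs = np.asarray(probs, dtype=float)
    ll = counts @ np.log(np.where(probs > 0, probs, 1.0)).T
    impossible = (counts > 0).astype(float) @ (probs == 0).astype(float).T
    ll = np.where(impossible > 0, -np.inf, ll)
    coef = gammaln(counts.sum(axis=1) + 1) - gammaln(counts + 1).sum(axis=1)
    return ll + coef[:, None]


def _single_locus_probs(tau: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Model probabilities on a grid, written independently of the package."""
    p_hom = tau * ((1.0 - beta) / 6.0 + beta / 2.0)
    p_am = 1.0 - 2.0 * p_hom
    return np.stack([p_hom, p_am, p_hom], axis=-1)


def grid_ml_tau(counts: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Brute-force grid argmax of the likelihood over tau (beta = 0).

    ``counts`` is (m, 3); returns (m,) tau estimates.
    """
    grid = np.arange(0.0, 1.0 + step / 2.0, step)
    probs = _single_locus_probs(grid, np.zeros_like(grid))
    ll = _multinomial_loglik(np.atleast_2d(counts), probs)
    return grid[np.argmax(ll, axis=1)]


def grid_ml_beta(counts: np.ndarray, tau: float, step: float = 1e-4) -> np.ndarray:
    """Brute-force grid argmax over beta in [0, 1/6] with tau fixed."""
    grid = np.arange(0.0, 1.0 / 6.0 + step / 2.0, step)
    probs = _single_locus_probs(np.full_like(grid, tau), grid)
    ll = _multinomial_loglik(np.atleast_2d(counts), probs)
    return grid[np.argmax(ll, axis=1)]


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, str]:
    """Random binary tree with uniform branch lengths; returns ids, the
    additive distance matrix, and the generating newick string."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # grow an unrooted binary tree by random subdivision, tracked as an
    # explicit edge-weighted graph
    import networkx as nx

    g = nx.Graph()
    g.add_edge(ids[0], ids[1], length=float(rng.uniform(0.5, 2.0)))
    internal = 0
    for taxon in ids[2:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        length = g[u][v]["length"]
        g.remove_edge(u, v)
        mid = f"x{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, length=length * split)
        g.add_edge(mid, v, length=length * (1.0 - split))
        g.add_edge(mid, taxon, length=float(rng.uniform(0.5, 2.0)))
    d = np.zeros((n_taxa, n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            d[i, j] = lengths[a][b]
    return ids, d, ""
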
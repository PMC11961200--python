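"""Method comparison on synthetic attractor data.

Generates random signed networks, enumerates their Boolean attractors and
asks each inference method to reconstruct the network from the attractor
patterns alone.  Methods compared: ESABO entropy-shift scoring, EDAME
refinement of the ESABO seed, and three generic pairwise-association
baselines (mutual information, Pearson correlation, phi coefficient).
ESABO and EDAME receive the true edge counts via top-``M+`` /
bottom-``M-`` count selection; the generic baselines keep every pair
whose association is significant at ``p < 0.05`` under the statistic's
canonical test (t-test for Pearson, the ``n * phi^2`` chi-square for phi
and for mutual information, which on 2x2 tables is a monotone transform
of ``|phi|``), signed by the score.  Accuracy is the
signed-edge Jaccard index against the ground-truth network.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import compute_attractors
from .esabo import EdgeSelection, esabo_network, esabo_scores
from .network import SignedNetwork, edge_jaccard, generate_random_network
from .refine import EdameConfig, edame_refine

__all__ = [
    "BASELINE_METHODS",
    "baseline_scores",
    "signed_baseline_scores",
    "baseline_pvalues",
    "baseline_network",
    "count_mode_network",
    "run_method_comparison",
    "comparison_medians",
]

BASELINE_METHODS = ("mutual_information", "pearson", "phi")


def _pair_counts(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """2x2 contingency counts (n11, n10, n01, n00) for every column pair."""
    x = x.astype(np.int64)
    n = x.shape[0]
    n11 = x.T @ x
    n1_ = x.sum(axis=0)
    n10 = n1_[:, None] - n11
    n01 = n1_[None, :] - n11
    n00 = n - n11 - n10 - n01
    return n11, n10, n01, n00


def _phi_matrix(x: np.ndarray) -> np.ndarray:
    n11, n10, n01, n00 = _pair_counts(x)
    num = n11 * n00 - n10 * n01
    den = np.sqrt(
        (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    ).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = num / den
    phi[den == 0] = np.nan
    np.fill_diagonal(phi, np.nan)
    return phi


def _mi_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise mutual information in bits from the 2x2 joint."""
    n = x.shape[0]
    counts = _pair_counts(x)
    p1 = x.mean(axis=0)
    marg_i = (p1[:, None], p1[:, None], 1 - p1[:, None], 1 - p1[:, None])
    marg_j = (p1[None, :], 1 - p1[None, :], p1[None, :], 1 - p1[None, :])
    mi = np.zeros((x.shape[1], x.shape[1]))
    for cell, mi_, mj_ in zip(counts, marg_i, marg_j):
        p = cell / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * np.log2(p / (mi_ * mj_))
        mi += np.where(p > 0, term, 0.0)
    degenerate = (p1 == 0) | (p1 == 1)
    mi[degenerate, :] = np.nan
    mi[:, degenerate] = np.nan
    np.fill_diagonal(mi, np.nan)
    return mi


def baseline_scores(patterns, method: str) -> np.ndarray:
    """Pairwise column-association matrix for one baseline method.

    ``pearson`` and ``phi`` are signed in [-1, 1] (and coincide on 0/1
    data); ``mutual_information`` is non-negative, in bits — its sign for
    edge-sign calls is taken from phi (see ``signed_baseline_scores``).
    Entries involving a constant column are NaN.
    """
    x = np.asarray(patterns)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("patterns must be 2-D with at least 2 samples")
    if method == "phi":
        return _phi_matrix(x)
    if method == "pearson":
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.corrcoef(x.astype(float), rowvar=False)
        sd = x.std(axis=0)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        np.fill_diagonal(r, np.nan)
        return r
    if method == "mutual_information":
        return _mi_matrix(x)
    raise ValueError(f"unknown baseline method {method!r}")


def signed_baseline_scores(patterns, method: str) -> np.ndarray:
    """Score matrix ready for top/bottom edge selection.

    For mutual information the (unsigned) MI is multiplied by the sign of
    the phi coefficient of the same pair; Pearson and phi are already
    signed.
    """
    scores = baseline_scores(patterns, method)
    if method == "mutual_information":
        scores = scores * np.sign(_phi_matrix(np.asarray(patterns)))
    return scores


def baseline_pvalues(patterns, method: str) -> np.ndarray:
    """Two-sided p-value of each pair's association under the canonical
    test for ``method``: t-test on r for Pearson, the 2x2 chi-square
    ``n * phi^2`` for phi and likewise for mutual information (on a 2x2
    table MI is a monotone transform of ``|phi|``)."""
    x = np.asarray(patterns)
    n = x.shape[0]
    if method == "pearson":
        r = baseline_scores(x, "pearson")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-12, None))
        return 2 * stats.t.sf(np.abs(t), n - 2)
    if method == "phi":
        phi = _phi_matrix(x)
        return stats.chi2.sf(n * phi**2, 1)
    if method == "mutual_information":
        # On 2x2 tables MI is a monotone transform of |phi|; the classical
        # chi-square approximation n*phi^2 ~ chi2(1) is used as for phi.
        phi = _phi_matrix(x)
        return stats.chi2.sf(n * phi**2, 1)
    raise ValueError(f"unknown baseline method {method!r}")


def baseline_network(
    patterns, method: str, alpha: float = 0.05
) -> SignedNetwork:
    """Significance-filtered baseline network: every pair significant at
    ``p < alpha`` becomes an edge signed by its (signed) score."""
    x = np.asarray(patterns)
    scores = signed_baseline_scores(x, method)
    pvals = baseline_pvalues(x, method)
    n = scores.shape[0]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            s = scores[i, j]
            if np.isfinite(s) and s != 0 and pvals[i, j] < alpha:
                edges.add((i, j, 1 if s > 0 else -1))
    return SignedNetwork(n, frozenset(edges))


def count_mode_network(scores: np.ndarray, n_pos: int, n_neg: int) -> SignedNetwork:
    """Top-``n_pos``/bottom-``n_neg`` selection, ties by ascending pair index."""
    n = scores.shape[0]
    pairs = [
        (i, j, float(scores[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(scores[i, j])
    ]
    if n_pos + n_neg > len(pairs):
        raise ValueError("not enough finite-score pairs for the requested counts")
    by_desc = sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))
    by_asc = sorted(pairs, key=lambda t: (t[2], t[0], t[1]))
    edges = {(i, j, 1) for i, j, _ in by_desc[:n_pos]}
    edges |= {(i, j, -1) for i, j, _ in by_asc[:n_neg]}
    return SignedNetwork(n, frozenset(edges))


def run_method_comparison(
    n_networks: int,
    net_params: tuple[int, int, int],
    cfg: EdameConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruction accuracy of each method over a random-network ensemble.

    Returns a tidy frame with one row per (method, replicate): the signed-
    edge Jaccard index of the inferred network against the ground truth,
    plus the attractor JI reached (for ESABO and EDAME).  EDAME optimizes
    the attractor overlap, not the edge overlap, so its edge JI is not
    guaranteed to dominate the ESABO seed's on every instance — only the
    attractor JI is monotone along its accepted moves.
    """
    if cfg is None:
        # the iteration limit is non-binding here (successful refinement
        # trajectories from ESABO seeds stay well below 100 moves)
        cfg = EdameConfig(iteration_limit=100, failure_limit=20)
    n_nodes, m_pos, m_neg = net_params
    root = np.random.default_rng(seed)
    rows = []
    for rep in range(n_networks):
        seeds = root.integers(0, 2**31 - 1, size=2)
        truth = generate_random_network(n_nodes, m_pos, m_neg, int(seeds[0]))
        target = compute_attractors(truth, cfg.attractor_cap)
        patterns = target.bit_matrix()

        esabo_net = esabo_network(
            esabo_scores(patterns), EdgeSelection(n_pos=m_pos, n_neg=m_neg)
        )
        from .compare import attractor_jaccard
        from .dynamics import AttractorSet

        # stationary-state overlap, the same objective EDAME optimizes
        esabo_attr_ji = attractor_jaccard(
            AttractorSet(n_nodes, target.fixed_points, ()),
            AttractorSet(
                n_nodes,
                compute_attractors(esabo_net, cfg.attractor_cap).fixed_points,
                (),
            ),
        )
        rows.append(
            ("esabo", rep, edge_jaccard(truth, esabo_net), esabo_attr_ji)
        )

        res = edame_refine(
            esabo_net, target, replace(cfg, seed=int(seeds[1])), reference_net=truth
        )
        rows.append(
            ("edame", rep, edge_jaccard(truth, res.final_network), res.final_ji)
        )

        for method in BASELINE_METHODS:
            net = baseline_network(patterns, method)
            rows.append((method, rep, edge_jaccard(truth, net), np.nan))
    return pd.DataFrame(
        rows, columns=["method", "replicate", "edge_ji", "attractor_ji"]
    )


def comparison_medians(table: pd.DataFrame) -> pd.Series:
    """Median signed-edge JI per method."""
    return table.groupby("method")["edge_ji"].median()
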
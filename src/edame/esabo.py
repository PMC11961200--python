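"""ESABO entropy-shift edge scoring on binary pattern matrices.

ESABO (Entropy Shifts of Abundance Vectors under Boolean Operations)
scores a candidate edge between taxa ``i`` and ``j`` by combining their
binary abundance columns with a Boolean AND across samples and asking how
surprising the Shannon entropy of the combined vector is under the null
hypothesis that the two columns are unrelated.

The null holds the per-column densities fixed (as in shuffling one column
relative to the other), so the number of co-occurrences ``k`` of two
columns with ``a`` and ``b`` ones over ``n`` samples follows the
hypergeometric law ``k ~ Hypergeom(n, a, b)``.  The null mean and standard
deviation of ``H(AND)`` are computed exactly by summing the binary entropy
``H(k/n)`` over that distribution, and the reported score is the z-like
standardization ``(H_obs - mu0) / sigma0``.  Positive scores indicate
co-presence above chance (synergy), negative scores avoidance
(competition).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.stats import hypergeom

from .network import SignedNetwork

__all__ = [
    "EsaboScoreMatrix",
    "EdgeSelection",
    "binary_entropy",
    "esabo_scores",
    "esabo_network",
    "load_binary_patterns",
]


@dataclass(frozen=True)
class EsaboScoreMatrix:
    """Symmetric N x N entropy-shift score matrix.

    The diagonal is NaN, as are pairs involving a degenerate (constant)
    column, which carry no co-occurrence information.
    """

    scores: np.ndarray
    degenerate_nodes: tuple = ()

    @property
    def n_nodes(self) -> int:
        return self.scores.shape[0]

    def finite_pairs(self):
        """Yield (i, j, score) over i<j pairs with a finite score."""
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                s = self.scores[i, j]
                if np.isfinite(s):
                    yield i, j, float(s)


@dataclass(frozen=True)
class EdgeSelection:
    """How to turn a score matrix into a signed network.

    Exactly one mode is active: count mode (``n_pos``/``n_neg`` highest and
    lowest scoring pairs, either integers or the string ``"random"`` drawn
    uniformly from ``random_range``) or threshold mode (``theta_pos``,
    ``theta_neg``).
    """

    n_pos: int | str | None = None
    n_neg: int | str | None = None
    theta_pos: float | None = None
    theta_neg: float | None = None
    random_range: tuple = (1, 10)

    def __post_init__(self) -> None:
        count_mode = self.n_pos is not None or self.n_neg is not None
        thresh_mode = self.theta_pos is not None or self.theta_neg is not None
        if count_mode == thresh_mode:
            raise ValueError(
                "exactly one of count mode (n_pos/n_neg) or threshold mode "
                "(theta_pos/theta_neg) must be specified"
            )
        if count_mode and (self.n_pos is None or self.n_neg is None):
            raise ValueError("count mode needs both n_pos and n_neg")
        if thresh_mode and (self.theta_pos is None or self.theta_neg is None):
            raise ValueError("threshold mode needs both theta_pos and theta_neg")

    @property
    def count_mode(self) -> bool:
        return self.n_pos is not None


def binary_entropy(k: np.ndarray, n: int) -> np.ndarray:
    """Shannon entropy (bits) of a binary vector with ``k`` ones of ``n``."""
    p = np.asarray(k, dtype=float) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log2(p)) - ((1 - p) * np.log2(1 - p))
    return np.where((p <= 0) | (p >= 1), 0.0, h)


def _null_moments(a: int, b: int, n: int) -> tuple[float, float]:
    """Exact null mean and sd of H(AND) for columns with a and b ones."""
    lo = max(0, a + b - n)
    hi = min(a, b)
    k = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(k, n, a, b)
    h = binary_entropy(k, n)
    mu = float(pmf @ h)
    var = float(pmf @ (h - mu) ** 2)
    return mu, np.sqrt(max(var, 0.0))


def esabo_scores(patterns) -> EsaboScoreMatrix:
    """Entropy-shift score for every node pair of a samples x N 0/1 matrix.

    Rows are samples (e.g. attractor states), columns are taxa.  Pairs
    involving a constant column, and pairs whose null entropy distribution
    is degenerate (zero null variance), get a NaN score and are excluded
    from edge selection.
    """
    x = np.asarray(patterns)
    if x.ndim != 2:
        raise ValueError("patterns must be a 2-D samples x nodes matrix")
    n_samples, n_nodes = x.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if np.any((x != 0) & (x != 1)):
        raise ValueError("patterns must be 0/1")
    x = x.astype(np.int64)

    ones = x.sum(axis=0)
    degenerate = [i for i in range(n_nodes) if ones[i] in (0, n_samples)]
    scores = np.full((n_nodes, n_nodes), np.nan)
    overlap = x.T @ x  # co-occurrence counts for every pair
    for i in range(n_nodes):
        if i in degenerate:
            continue
        for j in range(i + 1, n_nodes):
            if j in degenerate:
                continue
            mu, sd = _null_moments(int(ones[i]), int(ones[j]), n_samples)
            if sd == 0.0:
                continue
            h_obs = float(binary_entropy(np.array(overlap[i, j]), n_samples))
            scores[i, j] = scores[j, i] = (h_obs - mu) / sd
    return EsaboScoreMatrix(scores, tuple(degenerate))


def load_binary_patterns(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a samples x nodes 0/1 matrix from plain text.

    Accepts the whitespace-separated attractor-matrix format (no header)
    or a TSV whose first line names the taxa.  Returns the matrix and the
    taxon names (None when the file has no header).
    """
    with open(path) as fh:
        first = fh.readline()
    tokens = first.split()
    has_header = any(not t.lstrip("+-").isdigit() for t in tokens)
    if has_header:
        names = first.rstrip("\n").split("\t")
        data = np.loadtxt(path, dtype=np.int64, skiprows=1)
        return np.atleast_2d(data), names
    return np.atleast_2d(np.loadtxt(path, dtype=np.int64)), None


def _resolve_count(value, rng: np.random.Generator, rand_range: tuple) -> int:
    if value == "random":
        if rng is None:
            raise ValueError("'random' edge counts need an rng/seed")
        lo, hi = rand_range
        return int(rng.integers(lo, hi + 1))
    value = int(value)
    if value < 0:
        raise ValueError("edge counts must be non-negative")
    return value


def esabo_network(
    score_matrix: EsaboScoreMatrix,
    selection: EdgeSelection,
    seed: int | np.random.Generator | None = None,
) -> SignedNetwork:
    """Turn entropy-shift scores into a signed network.

    Count mode takes the ``n_pos`` highest-scoring pairs as positive edges
    and the ``n_neg`` lowest-scoring pairs as negative edges; threshold
    mode takes scores above ``theta_pos`` / below ``theta_neg``.  Ties at a
    selection boundary are broken by ascending pair index ``(i, j)``.
    """
    n = score_matrix.n_nodes
    pairs = list(score_matrix.finite_pairs())
    if selection.count_mode:
        rng = np.random.default_rng(seed)
        n_pos = _resolve_count(selection.n_pos, rng, selection.random_range)
        n_neg = _resolve_count(selection.n_neg, rng, selection.random_range)
        if n_pos + n_neg > len(pairs):
            raise ValueError(
                f"{n_pos}+{n_neg} edges requested but only {len(pairs)} "
                "pairs have finite scores"
            )
        by_desc = sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))
        by_asc = sorted(pairs, key=lambda t: (t[2], t[0], t[1]))
        edges = {(i, j, 1) for i, j, _ in by_desc[:n_pos]}
        edges |= {(i, j, -1) for i, j, _ in by_asc[:n_neg]}
    else:
        edges = {(i, j, 1) for i, j, s in pairs if s > selection.theta_pos}
        edges |= {(i, j, -1) for i, j, s in pairs if s < selection.theta_neg}
    return SignedNetwork(n, frozenset(edges))
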
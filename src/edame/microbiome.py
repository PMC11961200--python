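"""From abundance tables to attractors, and from inferred networks to
cohort summaries.

The real-data workflow treats a relative-abundance table (taxa x samples)
as observations of the asymptotic states of an underlying interaction
network: species rows are aggregated to the phylum level, entries are
binarized by a presence threshold, and the unique binary sample patterns
are interpreted as the attractor set handed to ESABO/EDAME.  Networks
inferred per study are then combined into JI-weighted cohort summary
networks, and a quality index compares how well an inference method
separates cohorts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dynamics import AttractorSet
from .network import SignedNetwork, edge_jaccard

__all__ = [
    "CohortNetworkSet",
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy_map",
    "aggregate_to_phylum",
    "binarize_to_attractors",
    "summary_network",
    "write_summary_network",
    "quality_index",
    "spearman_network",
]


@dataclass(frozen=True)
class CohortNetworkSet:
    """Networks inferred from the studies of one cohort, each with the
    attractor JI reached at the end of refinement."""

    label: str
    networks: tuple  # of (SignedNetwork, float ji)

    def __post_init__(self) -> None:
        for _, ji in self.networks:
            if not 0.0 <= ji <= 1.0:
                raise ValueError(f"attractor JI {ji} outside [0, 1]")


# -- abundance-table I/O (TSV, taxa rows x sample columns) ----------------


def read_abundance_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.has_duplicates:
        raise ValueError(f"{path}: duplicate taxon names")
    if (table.values < 0).any():
        raise ValueError(f"{path}: negative abundances")
    return table


def write_abundance_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_taxonomy_map(path) -> dict[str, str]:
    """Two-column TSV ``taxon<TAB>phylum`` (no header)."""
    mapping = pd.read_csv(path, sep="\t", header=None, names=["taxon", "phylum"])
    return dict(zip(mapping["taxon"], mapping["phylum"]))


def aggregate_to_phylum(
    table: pd.DataFrame, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Sum abundance rows to the phylum level (column sums are preserved)."""
    missing = [t for t in table.index if t not in taxonomy]
    if missing:
        raise KeyError(f"taxa without a phylum mapping: {missing}")
    phyla = table.index.map(taxonomy)
    out = table.groupby(phyla, sort=True).sum()
    out.index.name = table.index.name
    return out


def binarize_to_attractors(
    table: pd.DataFrame,
    threshold: float = 0.0,
    drop_empty: bool = False,
) -> tuple[AttractorSet, list[str]]:
    """Binarize samples and collapse duplicates into a pattern set.

    An entry becomes 1 when its abundance is strictly greater than
    ``threshold`` (default 0: plain presence/absence).  Each unique sample
    pattern becomes one state of a fixed-point-only :class:`AttractorSet`
    over the table's taxa (row ``k`` of the table is node ``k``).
    ``drop_empty`` removes the all-zero pattern, which is unobservable as
    a community.  Returns the pattern set and the node-ordered taxa list.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    taxa = list(table.index)
    n = len(taxa)
    binary = (table.values > threshold).astype(np.int64)
    states = set((binary.T @ (1 << np.arange(n, dtype=np.int64))).tolist())
    if drop_empty:
        states.discard(0)
    if not states:
        warnings.warn("binarization produced no patterns", stacklevel=2)
    return AttractorSet.from_states(n, states), taxa


def summary_network(cohort: CohortNetworkSet) -> pd.DataFrame:
    """JI-weighted superposition of one cohort's study networks.

    ``weight(i, j) = sum over studies of sign_study(i, j) * JI_study``;
    edges whose contributions cancel exactly are kept with weight 0
    dropped.  Returns a frame with columns ``i, j, weight``.
    """
    if not cohort.networks:
        raise ValueError("cohort has no networks")
    n_nodes = {net.n_nodes for net, _ in cohort.networks}
    if len(n_nodes) != 1:
        raise ValueError("cohort networks disagree on the node set")
    weights: dict[tuple[int, int], float] = {}
    for net, ji in cohort.networks:
        for i, j, s in net.edges:
            weights[(i, j)] = weights.get((i, j), 0.0) + s * ji
    rows = [
        (i, j, w) for (i, j), w in sorted(weights.items()) if w != 0.0
    ]
    return pd.DataFrame(rows, columns=["i", "j", "weight"])


def write_summary_network(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, header=False)


def quality_index(cohorts: Sequence[CohortNetworkSet]) -> float:
    """Within- vs. across-cohort network similarity ratio.

    QI = (mean pairwise signed-edge Jaccard within cohorts) /
    (mean pairwise signed-edge Jaccard across cohorts).  QI > 1 means an
    inference method produces more similar networks inside a cohort than
    between cohorts.  A zero across-cohort mean makes the ratio undefined
    and is reported as ``inf`` with a warning.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    for c in cohorts:
        if len(c.networks) < 2:
            raise ValueError(f"cohort {c.label!r} needs at least 2 networks")
    within = [
        edge_jaccard(a, b)
        for c in cohorts
        for (a, _), (b, _) in itertools.combinations(c.networks, 2)
    ]
    across = [
        edge_jaccard(a, b)
        for ca, cb in itertools.combinations(cohorts, 2)
        for a, _ in ca.networks
        for b, _ in cb.networks
    ]
    mean_within = float(np.mean(within))
    mean_across = float(np.mean(across))
    if mean_across == 0.0:
        warnings.warn(
            "across-cohort similarity is zero: QI undefined, reporting inf",
            stacklevel=2,
        )
        return float("inf")
    return mean_within / mean_across


def spearman_network(
    table: pd.DataFrame,
    threshold: float = 0.1,
    alpha: float = 0.05,
) -> SignedNetwork:
    """Thin correlation-network baseline on non-binarized abundances.

    An edge is drawn between two taxa when the Spearman correlation of
    their abundance rows is significant (p < ``alpha``) and its magnitude
    exceeds ``threshold``; the edge sign is the correlation's sign.
    """
    values = table.values.astype(float)
    n = values.shape[0]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            rho, p = spearmanr(values[i], values[j])
            if np.isfinite(rho) and p < alpha and abs(rho) > threshold:
                edges.add((i, j, 1 if rho > 0 else -1))
    return SignedNetwork(n, frozenset(edges))
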
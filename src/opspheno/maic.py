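"""Information-content meta-analysis of screen-derived gene lists.

Heterogeneous screens each nominate a gene list; no single screen is
ground truth.  The meta-analysis cross-weights them iteratively: a gene's
score is the sum, over evidence categories, of the best current weight
among that category's lists containing it (so multiple lists within one
category — e.g. technical near-replicates — are not double counted), and a
list's weight is the mean score of its member genes, rescaled so the best
list has weight 1.  At the fixed point, lists that share genes with other
informative lists carry high weight, and genes supported by several
independent categories outscore genes seen only once.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import GeneListCollection, GeneListSource

logger = logging.getLogger(__name__)

__all__ = ["Maic", "run_maic", "MaicResult", "prepare_gene_lists", "consensus_genes"]


class Maic(BaseEstimator):
    """Iterative gene-list cross-weighting (fit-shaped estimator).

    Fitted attributes: ``gene_scores_`` (descending Series),
    ``list_weights_`` (Series per source), ``n_iterations_``,
    ``converged_``.
    """

    def __init__(self, max_iterations: int = 100, tolerance: float = 1e-6):
        self.max_iterations = max_iterations
        self.tolerance = tolerance

    def fit(self, collection: GeneListCollection, y=None) -> "Maic":
        if len(collection.sources) < 1:
            raise ValueError("need at least one source")
        names = sorted(collection.sources)
        weights = {s: 1.0 for s in names}
        categories: dict[str, list[str]] = {}
        for s in names:
            categories.setdefault(collection.sources[s].category, []).append(s)
        membership = {s: set(collection.sources[s].genes) for s in names}
        genes = collection.all_genes()

        def update(w: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
            scores = {}
            for g in genes:
                total = 0.0
                for cat, srcs in categories.items():
                    best = max((w[s] for s in srcs if g in membership[s]), default=0.0)
                    total += best
                scores[g] = total
            new_w = {}
            for s in names:
                members = membership[s]
                new_w[s] = (
                    sum(scores[g] for g in members) / len(members) if members else 0.0
                )
                if not members:
                    logger.warning("source %s is empty; weight set to 0", s)
            top = max(new_w.values())
            if top > 0:
                new_w = {s: v / top for s, v in new_w.items()}
            return new_w, scores

        converged = False
        n_iter = 0
        scores: dict[str, float] = {}
        for n_iter in range(1, self.max_iterations + 1):
            new_weights, scores = update(weights)
            delta = max(abs(new_weights[s] - weights[s]) for s in names)
            weights = new_weights
            if delta < self.tolerance:
                converged = True
                break
        if not converged:
            logger.warning("meta-analysis did not converge in %d iterations", n_iter)

        # sort by name first so the stable value sort breaks ties by gene
        self.gene_scores_ = (
            pd.Series(scores, name="score")
            .sort_index()
            .sort_values(ascending=False, kind="stable")
        )
        self.list_weights_ = pd.Series(weights, name="weight").loc[names]
        self.n_iterations_ = n_iter
        self.converged_ = converged
        self._update = update  # kept for fixed-point verification
        return self

    def one_step(self) -> pd.Series:
        """Re-apply one update step to the converged weights (fixed-point
        check): returns the resulting weights."""
        w, _ = self._update(dict(self.list_weights_))
        return pd.Series(w, name="weight").loc[self.list_weights_.index]


class MaicResult:
    """Converged gene scores and list weights."""

    def __init__(self, est: Maic):
        self.gene_scores = est.gene_scores_
        self.list_weights = est.list_weights_
        self.n_iterations = est.n_iterations_
        self.converged = est.converged_
        self._est = est

    def one_step(self) -> pd.Series:
        return self._est.one_step()


def run_maic(
    collection: GeneListCollection,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
) -> MaicResult:
    """Run the meta-analysis to its weight/score fixed point."""
    return MaicResult(Maic(max_iterations, tolerance).fit(collection))


def prepare_gene_lists(
    hit_tables: Mapping[str, pd.DataFrame],
    top_n: int = 500,
    p_cut: float = 0.05,
) -> GeneListCollection:
    """Turn per-screen result tables into ranked meta-analysis inputs.

    Each table needs ``gene`` and ``p`` columns and may carry a
    ``direction`` column (bidirectional screens produce one source per
    direction).  Genes significant at ``p < p_cut`` are ranked by p and
    truncated to ``top_n``.  Each screen is its own category.
    """
    sources: dict[str, GeneListSource] = {}
    for screen, table in hit_tables.items():
        groups = (
            table.groupby("direction", observed=True)
            if "direction" in table.columns
            else [(None, table)]
        )
        for direction, df in groups:
            sig = df[df["p"] < p_cut].sort_values(["p", "gene"], kind="stable")
            genes = list(dict.fromkeys(sig["gene"]))[:top_n]
            name = screen if direction is None else f"{screen}_{direction}"
            if not genes:
                logger.warning("screen %s: no genes pass p < %g", name, p_cut)
            sources[name] = GeneListSource(category=screen, ranked=True, genes=genes)
    return GeneListCollection(sources)


def consensus_genes(
    hit_sets: Mapping[str, Sequence[str]],
    min_screens: int = 2,
) -> list[str]:
    """Genes scoring in at least ``min_screens`` screens, sorted by how
    many screens support them (descending), then by name."""
    counts: dict[str, int] = {}
    for genes in hit_sets.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    hits = [(g, c) for g, c in counts.items() if c >= min_screens]
    hits.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in hits]
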
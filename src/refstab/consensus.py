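"""Consensus ranking of candidate reference genes across algorithms.

Each algorithm's ordering (most to least stable) is converted into integer
weights 1..G; tied positions share the mean of the spanned integers (e.g. a
tied best pair gets 1.5 each).  A gene's consensus score is the geometric
mean of its weights across methods, GM_i = (prod_m w_im)^(1/M), and the
final order sorts GM ascending — the gene with the lowest GM is the most
stable overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusRanking",
    "assign_weights",
    "geometric_mean_rank",
    "consensus_rank",
]


def _expand_order(order: Sequence) -> dict:
    """Ordered genes (elements may be tuples/sets of tied genes) -> weights."""
    weights: dict = {}
    position = 1
    for element in order:
        if isinstance(element, (tuple, list, set, frozenset)):
            tied = list(element)
        else:
            tied = [element]
        span = range(position, position + len(tied))
        mean_weight = sum(span) / len(tied)
        for gene in tied:
            if gene in weights:
                raise ValueError(f"gene {gene!r} listed twice in one ranking")
            weights[gene] = mean_weight
        position += len(tied)
    return weights


def assign_weights(orders: Mapping[str, Sequence]) -> pd.DataFrame:
    """Per-method rank weights (genes x methods) from stability orderings.

    ``orders`` maps method name -> genes most-stable-first; an element may
    be a tuple of genes to mark a tie.  All methods must rank the same gene
    set.
    """
    if not orders:
        raise ValueError("at least one method ranking is required")
    columns = {}
    gene_sets = {}
    first_genes: list | None = None
    for method, order in orders.items():
        weights = _expand_order(order)
        columns[method] = weights
        gene_sets[method] = set(weights)
        if first_genes is None:
            first_genes = list(weights)
    reference = gene_sets[next(iter(gene_sets))]
    for method, genes in gene_sets.items():
        if genes != reference:
            raise ValueError(
                f"method {method!r} ranks a different gene set: "
                f"{sorted(genes ^ reference)}"
            )
    frame = pd.DataFrame(columns, index=first_genes, dtype=float)
    frame.index.name = "gene"
    return frame


@dataclass
class ConsensusRanking:
    """Geometric-mean consensus over per-method rank weights."""

    per_method_ranks: pd.DataFrame  # genes x methods
    gm: pd.Series
    final_order: list  # most stable first

    def to_dict(self) -> dict:
        return {
            "per_method_ranks": {
                str(m): {g: float(v) for g, v in self.per_method_ranks[m].items()}
                for m in self.per_method_ranks.columns
            },
            "gm": {g: float(v) for g, v in self.gm.items()},
            "final_order": list(self.final_order),
        }

    def to_frame(self) -> pd.DataFrame:
        out = self.per_method_ranks.loc[self.final_order].copy()
        out["gm"] = self.gm.loc[self.final_order]
        out["consensus_rank"] = range(1, len(out) + 1)
        return out.reset_index()


def geometric_mean_rank(per_method_ranks) -> ConsensusRanking:
    """Consensus ranking by ascending geometric mean of per-method weights.

    Requires >=2 methods and strictly positive weights.  GM ties break by
    mean per-method weight, then by input gene order (documented policy;
    the tie-break rarely fires with real stability values).
    """
    frame = pd.DataFrame(per_method_ranks, dtype=float)
    if frame.shape[1] < 2:
        raise ValueError("consensus needs >=2 methods")
    if (frame.to_numpy() <= 0).any():
        raise ValueError("rank weights must be positive")
    gm = pd.Series(
        np.exp(np.log(frame.to_numpy()).mean(axis=1)), index=frame.index
    )
    order_frame = pd.DataFrame(
        {
            "gm": gm,
            "mean_weight": frame.mean(axis=1),
            "input_pos": range(len(frame)),
        }
    )
    final = list(
        order_frame.sort_values(
            ["gm", "mean_weight", "input_pos"], kind="stable"
        ).index
    )
    return ConsensusRanking(per_method_ranks=frame, gm=gm, final_order=final)


def consensus_rank(orders: Mapping[str, Sequence]) -> ConsensusRanking:
    """Convenience wrapper: orderings -> weights -> geometric-mean consensus."""
    return geometric_mean_rank(assign_weights(orders))
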
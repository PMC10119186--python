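"""Pathway-consensus gene prioritization.

Combines externally produced pathway/enrichment outputs (consumed as
standardized tables, one per method): the strict intersection of each
method's prioritized gene set, a biological-importance score counting known
disease genes across significant pathways and modules, and the joint
top-fraction rule crossing that score with association p-values.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["intersect_methods", "importance_score", "score_table",
           "joint_top_fraction"]


def intersect_methods(
    method_sets: Mapping[str, Sequence[str]],
) -> tuple[set[str], pd.DataFrame]:
    """Genes present in every method's prioritized set, plus hit counts.

    Returns the strict consensus and a per-gene table of method-hit counts
    for relaxed (k-of-n) consensus.  An empty intersection is a valid
    outcome and is logged.
    """
    if len(method_sets) < 2:
        raise ValueError("need at least 2 methods to intersect")
    sets = {m: set(g) for m, g in method_sets.items()}
    consensus = set.intersection(*sets.values())
    if not consensus:
        logger.info("method intersection is empty")
    all_genes = sorted(set.union(*sets.values()))
    counts = pd.DataFrame(
        {
            "gene": all_genes,
            "n_methods": [sum(g in s for s in sets.values()) for g in all_genes],
        }
    )
    return consensus, counts.sort_values(
        ["n_methods", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def importance_score(
    gene: str,
    pathway_sets: pd.DataFrame,
    known: set[str] | Sequence[str],
) -> int:
    """Biological-importance score for one gene.

    Sums, over all *significant* pathways/modules (any method) containing
    the gene, the number of known disease genes among the pathway members.
    ``pathway_sets`` columns: method, pathway_id, members (iterable of gene
    ids), significant (bool).  A gene in no pathway scores 0.
    """
    known = set(known)
    score = 0
    for _, row in pathway_sets.iterrows():
        if not row["significant"]:
            continue
        members = set(row["members"])
        if gene in members:
            score += len(members & known)
    return score


def score_table(
    genes: Sequence[str], pathway_sets: pd.DataFrame, known: set[str]
) -> pd.DataFrame:
    """Importance scores for a gene list (vectorized convenience)."""
    return pd.DataFrame(
        {
            "gene": list(genes),
            "score": [importance_score(g, pathway_sets, known) for g in genes],
        }
    )


def joint_top_fraction(
    scores: pd.Series | Mapping[str, float],
    assoc_p: pd.Series | Mapping[str, float],
    fraction: float = 0.10,
) -> set[str]:
    """Genes in the top ``fraction`` by score AND by association p-value.

    Scores rank descending, p-values ascending; both rankings must cover
    the same gene universe.  Ties at either boundary are resolved
    inclusively (every tied gene enters), so the output can slightly exceed
    the nominal fraction; this avoids arbitrary ordering effects.
    """
    scores = pd.Series(scores, dtype=float)
    assoc_p = pd.Series(assoc_p, dtype=float)
    if set(scores.index) != set(assoc_p.index):
        raise ValueError("score and p-value rankings must cover the same genes")
    n = len(scores)
    n_top = max(1, int(np.ceil(fraction * n)))
    score_cut = scores.sort_values(ascending=False).iloc[n_top - 1]
    p_cut = assoc_p.sort_values(ascending=True).iloc[n_top - 1]
    top_score = set(scores.index[scores >= score_cut])
    top_p = set(assoc_p.index[assoc_p <= p_cut])
    return top_score & top_p
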
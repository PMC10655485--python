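"""Tissue-specificity diagnostics of the latent clustering.

The matrix of associations tabulates, for every mixture component, the
percentage of its samples contributed by each tissue; the component's
majority tissue defines the "correct" tissue for query matching. A query
sample matches if its assigned component's majority tissue equals its own
label; tissues represented by several components count a match to any of
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AssociationMatrix", "association_matrix", "tissue_match_percentage"]


@dataclass
class AssociationMatrix:
    percentages: pd.DataFrame  # tissues × components, columns sum to 100
    component_counts: pd.Series  # samples per (non-empty) component
    tissue_counts: pd.Series  # samples per tissue
    majority_map: dict[int, str]  # component → majority tissue


def association_matrix(assignments, tissues) -> AssociationMatrix:
    """Percentage of each component's samples belonging to each tissue.

    ``entry(t, c) = 100 · #{samples of tissue t in component c} /
    #{samples in component c}``. Components with no assigned samples are
    omitted (they have no defined column). Majority-tissue ties resolve
    toward the tissue with the larger total cohort, then lexicographically.
    """
    assignments = np.asarray(assignments)
    tissues = np.asarray(tissues)
    if assignments.shape[0] != tissues.shape[0]:
        raise ValueError("assignments and tissue labels must have equal length")

    crosstab = pd.crosstab(pd.Series(tissues, name="tissue"),
                           pd.Series(assignments, name="component"))
    comp_counts = crosstab.sum(axis=0)
    pct = 100.0 * crosstab / comp_counts

    tissue_counts = pd.Series(tissues).value_counts()
    majority: dict[int, str] = {}
    for comp in pct.columns:
        col = pct[comp]
        top = col[col == col.max()].index
        if len(top) > 1:  # tie → larger cohort, then name
            top = sorted(top, key=lambda t: (-tissue_counts[t], t))
        majority[int(comp)] = str(top[0])

    return AssociationMatrix(
        percentages=pct,
        component_counts=comp_counts,
        tissue_counts=tissue_counts,
        majority_map=majority,
    )


def tissue_match_percentage(
    query_assignments, query_tissues, majority_map: dict[int, str]
) -> pd.Series:
    """Per-tissue percentage of query samples landing in a component whose
    majority tissue matches their own label.

    A tissue backed by several components counts a match to any of them.
    Query samples assigned to a component absent from ``majority_map``
    count as unmatched.
    """
    query_assignments = np.asarray(query_assignments)
    query_tissues = np.asarray(query_tissues)
    if query_assignments.shape[0] != query_tissues.shape[0]:
        raise ValueError("assignments and tissue labels must have equal length")

    matched = np.array(
        [
            majority_map.get(int(c)) == t
            for c, t in zip(query_assignments, query_tissues)
        ]
    )
    out = {}
    for tissue in np.unique(query_tissues):
        mask = query_tissues == tissue
        out[str(tissue)] = 100.0 * matched[mask].mean()
    return pd.Series(out, name="percent_matched").sort_index()
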
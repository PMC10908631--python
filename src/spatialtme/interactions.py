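"""Cell-type pair interaction counting on spatial graphs.

Every undirected edge of a sample's spatial graph contributes one count to
exactly one unordered type pair (e.g. neutrophil–neutrophil,
neutrophil–tumor), so the pair counts always sum to the number of edges.
Because the field has no single convention for normalizing such counts,
the table carries both the raw count and a per-focal-cell normalization
(count divided by the number of cells of the pair's first type).
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .graphs import SpatialGraph
from .stats import unpaired_t_test
from .synthetic import CELL_TYPES

__all__ = ["count_pair_interactions", "interaction_matrix", "compare_interactions"]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def count_pair_interactions(graph: SpatialGraph, labels: pd.Series,
                            types=CELL_TYPES) -> pd.DataFrame:
    """Count graph edges per unordered cell-type pair.

    Returns one row per type pair (all pairs over ``types``, zeros
    included) with columns ``sample_id, type_a, type_b, count,
    normalized_count`` where ``type_a <= type_b`` alphabetically and
    ``normalized_count = count / n_cells(type_a)`` (NaN when the sample
    has no cells of ``type_a``).
    """
    node_ids = graph.node_ids
    missing = set(map(int, node_ids)) - set(map(int, labels.index))
    if missing:
        raise KeyError(f"unlabeled graph nodes, e.g. {sorted(missing)[:5]}")
    lab = labels.loc[node_ids]
    counts: dict[tuple[str, str], int] = {
        pair: 0 for pair in combinations_with_replacement(sorted(types), 2)}
    if graph.n_edges:
        la = labels.loc[graph.edges[:, 0]].to_numpy()
        lb = labels.loc[graph.edges[:, 1]].to_numpy()
        for a, b in zip(la, lb):
            counts[_pair_key(a, b)] += 1
    n_of_type = lab.value_counts()
    rows = []
    for (a, b), c in counts.items():
        na = int(n_of_type.get(a, 0))
        rows.append({"sample_id": graph.sample_id, "type_a": a, "type_b": b,
                     "count": c,
                     "normalized_count": c / na if na > 0 else np.nan})
    return pd.DataFrame(rows)


def interaction_matrix(table: pd.DataFrame, types=CELL_TYPES,
                       value: str = "count") -> pd.DataFrame:
    """Symmetric type-by-type matrix view of one sample's interaction table."""
    types = sorted(types)
    m = pd.DataFrame(0.0, index=types, columns=types)
    for row in table.itertuples(index=False):
        m.at[row.type_a, row.type_b] = getattr(row, value)
        m.at[row.type_b, row.type_a] = getattr(row, value)
    return m


def compare_interactions(tables: pd.DataFrame, pair: tuple[str, str],
                         groups: dict[str, str],
                         normalized: bool = False,
                         variant: str = "welch"):
    """Compare one type pair's per-sample interaction counts between groups.

    ``tables`` is the concatenation of per-sample interaction tables;
    ``groups`` maps sample id -> group label.  Returns a dict with group
    means/sds and the unpaired t-test result (degenerate tests — e.g. the
    pair absent from every sample — are flagged on the result).
    """
    a, b = _pair_key(*pair)
    col = "normalized_count" if normalized else "count"
    sub = tables[(tables["type_a"] == a) & (tables["type_b"] == b)]
    sub = sub.set_index("sample_id")[col]
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    values = {g: sub[[s for s in sub.index if groups[s] == g]].to_numpy(dtype=float)
              for g in group_names}
    for g, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 samples")
    test = unpaired_t_test(values[group_names[0]], values[group_names[1]],
                           variant=variant)
    return {
        "pair": (a, b),
        "value": col,
        "groups": group_names,
        "means": {g: float(np.mean(v)) for g, v in values.items()},
        "sds": {g: float(np.std(v, ddof=1)) for g, v in values.items()},
        "test": test,
    }
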
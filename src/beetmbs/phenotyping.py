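"""Cyst-count phenotype processing: SN transform, block-adjusted line
means, within-line CV, and extreme-pool selection.

Cyst counts ``n`` are variance-stabilized as ``SN = sqrt(n + 3/8)``
(Anscombe-type square-root transform).  Box effects of the randomized
incomplete-block design are removed with an additive two-way fit
(line + block) by alternating least squares; adjusted plant values are
``SN - block effect`` and a line's adjusted mean is the mean of its
adjusted plant values.  The coefficient of variation of a line's adjusted
plant values screens F2:3 families for residual segregation before the
phenotypic extremes are pooled for sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "sn_transform",
    "adjusted_means",
    "line_cv",
    "select_extremes",
    "DisconnectedDesignError",
    "PoolAssignment",
]


class DisconnectedDesignError(ValueError):
    """The block design splits into groups of lines that share no block."""

    def __init__(self, groups: list[set]):
        self.groups = groups
        desc = "; ".join(sorted(",".join(sorted(g)) for g in groups))
        super().__init__(f"design is disconnected; block groups: {desc}")


def sn_transform(n):
    """SN = sqrt(n + 3/8) for non-negative cyst counts (scalar or array)."""
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cyst counts must be non-negative")
    out = np.sqrt(arr + 0.375)
    return float(out) if np.isscalar(n) or arr.ndim == 0 else out


def _check_connected(table: pd.DataFrame) -> None:
    g = nx.Graph()
    g.add_edges_from(
        ("L:" + l, "B:" + b) for l, b in zip(table["line_id"], table["block_id"])
    )
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        block_groups = [
            {n[2:] for n in comp if n.startswith("B:")} for comp in comps
        ]
        raise DisconnectedDesignError(block_groups)


def adjusted_means(
    table: pd.DataFrame,
    value: str = "SN",
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit SN = line + block additively and remove block effects.

    Alternating least squares: given block effects, line effects are
    per-line means of the partial residual, and vice versa; block effects
    are centered to mean zero across blocks so a single-block design
    reduces to raw means.  Iterates to ``max|change| < tol`` or
    ``max_iter`` sweeps; on balanced designs this coincides with the
    two-way least-squares (and mixed-model adjusted-mean) solution.

    Parameters
    ----------
    table
        Plant-level frame with line_id, block_id and the value column
        (``SN``; computed from ``cysts`` if absent).
    value
        Column holding the transformed response.

    Returns
    -------
    summary, plants
        ``summary``: line_id, adjusted_mean, cv, n_plants, rank (rank 1 =
        lowest adjusted mean, ties by line_id).  ``plants``: the input
        plus ``block_effect`` and ``adjusted`` columns.
    """
    table = table.copy()
    if value not in table and "cysts" in table:
        table[value] = sn_transform(table["cysts"].to_numpy())
    if table["line_id"].nunique() < 2:
        raise ValueError("need at least two lines")
    _check_connected(table)

    y = table[value].to_numpy(float)
    line_codes, lines = pd.factorize(table["line_id"], sort=True)
    block_codes, blocks = pd.factorize(table["block_id"], sort=True)
    n_lines, n_blocks = len(lines), len(blocks)

    line_eff = np.zeros(n_lines)
    block_eff = np.zeros(n_blocks)
    line_cnt = np.bincount(line_codes, minlength=n_lines)
    block_cnt = np.bincount(block_codes, minlength=n_blocks)
    for _ in range(max_iter):
        new_line = np.bincount(line_codes, y - block_eff[block_codes], n_lines) / line_cnt
        new_block = np.bincount(block_codes, y - new_line[line_codes], n_blocks) / block_cnt
        new_block -= new_block.mean()
        delta = max(
            np.abs(new_line - line_eff).max(), np.abs(new_block - block_eff).max()
        )
        line_eff, block_eff = new_line, new_block
        if delta < tol:
            break

    plants = table.copy()
    plants["block_effect"] = block_eff[block_codes]
    plants["adjusted"] = y - plants["block_effect"]

    grp = plants.groupby("line_id")["adjusted"]
    summary = pd.DataFrame(
        {
            "line_id": lines,
            "adjusted_mean": grp.mean().reindex(lines).to_numpy(),
            "cv": [
                line_cv(v.to_numpy()) if len(v) >= 2 else float("nan") for _, v in grp
            ],
            "n_plants": grp.size().reindex(lines).to_numpy(),
        }
    )
    order = summary.sort_values(["adjusted_mean", "line_id"]).index
    summary.loc[order, "rank"] = np.arange(1, len(summary) + 1)
    summary["rank"] = summary["rank"].astype(int)
    return summary, plants


def line_cv(values: np.ndarray) -> float:
    """Sample SD / mean of one line's adjusted plant values.

    NaN (undefined, to be flagged downstream) when the mean is <= 0;
    requires at least two plants.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least two plants")
    m = values.mean()
    if m <= 0:
        return float("nan")
    return float(values.std(ddof=1) / m)


@dataclass(frozen=True)
class PoolAssignment:
    """Disjoint extreme pools: low adjusted means = tolerant, high = susceptible."""

    tolerant: tuple[str, ...]
    susceptible: tuple[str, ...]


def select_extremes(
    summary: pd.DataFrame,
    k_tolerant: int = 20,
    k_susceptible: int = 16,
    cv_max: float = 0.3,
) -> PoolAssignment:
    """Pick the phenotypic extremes among phenotypically homogeneous lines.

    Lines with CV <= cv_max (a defined CV — the segregation screen) are
    eligible; the k_tolerant lowest and k_susceptible highest adjusted
    means are returned, ties broken by lexicographically smaller line_id.
    """
    eligible = summary[summary["cv"].notna() & (summary["cv"] <= cv_max)]
    if k_tolerant + k_susceptible > len(eligible):
        raise ValueError(
            f"pools of {k_tolerant}+{k_susceptible} exceed {len(eligible)} eligible lines"
        )
    asc = eligible.sort_values(["adjusted_mean", "line_id"])
    tolerant = tuple(asc["line_id"].head(k_tolerant))
    desc = eligible.sort_values(
        ["adjusted_mean", "line_id"], ascending=[False, True]
    )
    susceptible = tuple(desc["line_id"].head(k_susceptible))
    if set(tolerant) & set(susceptible):
        raise ValueError("tolerant and susceptible pools overlap; population too small")
    return PoolAssignment(tolerant=tolerant, susceptible=susceptible)
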
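"""Nestedness of the tissue x ASV presence/absence matrix.

Two metrics are provided: NODF (overlap and decreasing fill; 0 = no nesting,
100 = perfect nesting, pairs with equal marginal totals score 0) and a matrix
"temperature" in [0, 100] (0 = perfectly nested packed matrix, larger = more
disordered). The temperature is an in-repo variant of the classic
matrix-temperature construction: the matrix is packed by decreasing marginal
totals and mapped to the unit square, a fill-determined isocline separates
expected presences from expected absences, and the temperature is the mean
squared relative isocline distance of the unexpected cells, normalized by
the all-cells-unexpected bound. Lines with tied marginal totals are averaged
uniformly over their tie block's packed positions, so the value never
depends on the input's row or column order. Its
contract is the set of properties (zero for perfect nesting, monotone growth
under de-nesting, bounded range), not numeric equality with any legacy
program.

Significance is assessed against an occurrence-preserving null model: each
ASV keeps its number of tissue occurrences, but which tissues it occupies is
drawn uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AsvCountTable, SampleMetadata


@dataclass
class PresenceMatrix:
    """Binary tissue x ASV incidence with labels; all-zero columns dropped."""

    row_ids: list[str]
    col_ids: list[str]
    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        self.m = m.astype(np.int8)

    @property
    def fill(self) -> float:
        return float(self.m.mean()) if self.m.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.m, index=self.row_ids, columns=self.col_ids)


@dataclass
class NestednessResult:
    nodf: float
    temperature: float
    fill: float
    null_temperatures: np.ndarray
    p_value: float
    n_sims: int


def build_presence_matrix(
    table: AsvCountTable, meta: SampleMetadata, level: str = "tissue"
) -> PresenceMatrix:
    """Presence = nonzero count in at least one sample of the group."""
    groups = meta.table[level].loc[table.counts.index]
    presence = (table.counts > 0).groupby(groups).any()
    keep = presence.any(axis=0)
    presence = presence.loc[:, keep]
    return PresenceMatrix(
        row_ids=list(presence.index),
        col_ids=list(presence.columns),
        m=presence.to_numpy().astype(np.int8),
    )


# ---------------------------------------------------------------------------
# NODF


def _nodf_axis(m: np.ndarray) -> tuple[float, int]:
    """Sum of paired row scores and number of row pairs for one orientation."""
    totals = m.sum(axis=1)
    overlap = (m.astype(np.int64) @ m.T.astype(np.int64)).astype(float)
    n = m.shape[0]
    n_pairs = n * (n - 1) // 2
    # ordered pairs (i richer, j strictly poorer and non-empty)
    strict = (totals[:, None] > totals[None, :]) & (totals[None, :] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(strict, 100.0 * overlap / totals[None, :], 0.0)
    return float(scores.sum()), n_pairs


def nodf(pm: PresenceMatrix | np.ndarray) -> float:
    """NODF over all row pairs and column pairs; equal marginals score 0."""
    m = pm.m if isinstance(pm, PresenceMatrix) else np.asarray(pm)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    row_sum, row_pairs = _nodf_axis(m)
    col_sum, col_pairs = _nodf_axis(m.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


# ---------------------------------------------------------------------------
# temperature


def _tie_probabilities(totals: np.ndarray) -> np.ndarray:
    """Row-stochastic matrix P with P[i, p] = probability that line i occupies
    packed position p, uniform over the positions of its marginal-total tie
    block. Lines with distinct totals get exactly one position."""
    totals = np.asarray(totals)
    n = totals.size
    sorted_tot = np.sort(totals)[::-1]
    p = np.zeros((n, n))
    for i, t in enumerate(totals):
        pos = np.flatnonzero(sorted_tot == t)
        p[i, pos] = 1.0 / pos.size
    return p


def _isocline_threshold(fill: float) -> float:
    """c such that the area of {u + v <= c} in the unit square equals fill."""
    if fill <= 0.5:
        return float(np.sqrt(2.0 * fill))
    return float(2.0 - np.sqrt(2.0 * (1.0 - fill)))


def _unexpectedness(m: np.ndarray) -> float:
    """Expected mean squared relative isocline distance of unexpected cells.

    Cell positions come from packing by decreasing marginal totals; lines
    whose totals tie are averaged uniformly over their tie block's positions,
    which makes the value exactly invariant to the input's row/column order.
    """
    rows, cols = m.shape
    fill = m.mean()
    c = _isocline_threshold(fill)
    u = (np.arange(cols) + 0.5) / cols
    v = (np.arange(rows) + 0.5) / rows
    s = v[:, None] + u[None, :]
    above = s > c  # expected-absence side
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(above, (s - c) / (2.0 - c), (c - s) / c)
    rel2 = rel**2
    a = rel2 * above        # positional contribution of a presence (1) cell
    b = rel2 * ~above       # positional contribution of an absence (0) cell
    p_row = _tie_probabilities(m.sum(axis=1))
    p_col = _tie_probabilities(m.sum(axis=0))
    expected_a = p_row @ a @ p_col.T
    expected_b = p_row @ b @ p_col.T
    return float(np.where(m == 1, expected_a, expected_b).mean())


def _unexpectedness_bound(shape: tuple[int, int], fill: float) -> float:
    """Same quantity with every cell counted as unexpected (normalizer)."""
    rows, cols = shape
    c = _isocline_threshold(fill)
    u = (np.arange(cols) + 0.5) / cols
    v = (np.arange(rows) + 0.5) / rows
    s = v[:, None] + u[None, :]
    above = s > c
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(above, (s - c) / (2.0 - c), (c - s) / c)
    return float((rel**2).mean())


def nestedness_temperature(pm: PresenceMatrix | np.ndarray) -> float:
    """Disorder of the packed presence matrix, in [0, 100]; lower = more nested."""
    m = pm.m if isinstance(pm, PresenceMatrix) else np.asarray(pm)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    fill = float(m.mean())
    if fill in (0.0, 1.0):
        return 0.0
    bound = _unexpectedness_bound(m.shape, fill)
    if bound == 0.0:
        return 0.0
    return 100.0 * _unexpectedness(m) / bound


# ---------------------------------------------------------------------------
# null model and significance


def null_model_occurrence_preserving(
    pm: PresenceMatrix, n_sims: int = 1000, seed: int = 0
) -> np.ndarray:
    """Temperatures of matrices with column totals fixed, rows randomized.

    Each ASV (column) keeps its number of occupied tissues; which tissues it
    occupies is re-drawn uniformly without replacement per simulation.
    """
    m = pm.m
    rows, cols = m.shape
    col_totals = m.sum(axis=0)
    if (col_totals > rows).any():
        raise ValueError("column total exceeds number of rows")
    rng = np.random.default_rng(seed)
    temps = np.empty(n_sims)
    for k in range(n_sims):
        sim = np.zeros_like(m)
        # ranking a uniform matrix gives a uniform choice of rows per column
        order = np.argsort(rng.random((rows, cols)), axis=0)
        for j in range(cols):
            sim[order[: col_totals[j], j], j] = 1
        temps[k] = nestedness_temperature(sim)
    return temps


def nestedness_significance(
    observed_temperature: float, null_temperatures: np.ndarray
) -> float:
    """One-sided p for "more nested than null" (lower temperature)."""
    null_temperatures = np.asarray(null_temperatures)
    if null_temperatures.size == 0:
        raise ValueError("empty null sample")
    n = null_temperatures.size
    return (1 + int((null_temperatures <= observed_temperature).sum())) / (n + 1)


def nestedness_analysis(
    table: AsvCountTable,
    meta: SampleMetadata,
    n_sims: int = 1000,
    seed: int = 0,
    level: str = "tissue",
) -> NestednessResult:
    """Presence matrix -> NODF, temperature and occurrence-preserving null test."""
    pm = build_presence_matrix(table, meta, level=level)
    temp = nestedness_temperature(pm)
    nulls = null_model_occurrence_preserving(pm, n_sims=n_sims, seed=seed)
    return NestednessResult(
        nodf=nodf(pm),
        temperature=temp,
        fill=pm.fill,
        null_temperatures=nulls,
        p_value=nestedness_significance(temp, nulls),
        n_sims=n_sims,
    )
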
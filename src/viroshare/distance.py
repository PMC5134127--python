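"""Sorensen / Bray-Curtis virome distances, PCoA, and household comparisons.

The Sorensen similarity of two viromes A, B is computed from the reciprocal
homology hits: (hits A->B + hits B->A) / (n_A + n_B), the classic 2C/(S1+S2)
coefficient when hits are reciprocal. It runs 0 (no sharing) to 1 (identical
viromes). The Bray-Curtis distance used for ordination is its complement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cohort import SampleKey
from .homology import SharedFractionRecord, SharedFractionTable

logger = logging.getLogger(__name__)


def sorensen_similarity(rec_ab: SharedFractionRecord, rec_ba: SharedFractionRecord) -> float:
    """Sorensen similarity of one unordered virome pair from its two ordered records."""
    if rec_ab.query_key != rec_ba.target_key or rec_ab.target_key != rec_ba.query_key:
        raise ValueError(
            "records do not describe the same unordered pair: "
            f"{rec_ab.query_key.label}->{rec_ab.target_key.label} vs "
            f"{rec_ba.query_key.label}->{rec_ba.target_key.label}"
        )
    n_total = rec_ab.n_query_contigs + rec_ba.n_query_contigs
    if n_total == 0:
        raise ValueError("both viromes are empty")
    return (rec_ab.n_query_with_hit + rec_ba.n_query_with_hit) / n_total


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix over sample keys, values in [0, 1]."""

    keys: tuple[SampleKey, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.keys), len(self.keys)):
            raise ValueError("matrix shape does not match the number of keys")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def value(self, a: SampleKey, b: SampleKey) -> float:
        i, j = self.keys.index(a), self.keys.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        labels = [k.label for k in self.keys]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def sorensen_matrix(table: SharedFractionTable) -> DistanceMatrix:
    """Pairwise Sorensen similarities (diagonal 1) from a complete ordered table."""
    keys = table.keys
    n = len(keys)
    values = np.ones((n, n))
    for i, a in enumerate(keys):
        for j in range(i + 1, n):
            b = keys[j]
            s = sorensen_similarity(table.record(a, b), table.record(b, a))
            values[i, j] = values[j, i] = s
    return DistanceMatrix(keys=keys, values=values)


def bray_curtis_matrix(table: SharedFractionTable) -> DistanceMatrix:
    """Bray-Curtis distances: 1 - Sorensen, diagonal forced to 0."""
    sim = sorensen_matrix(table)
    values = 1.0 - sim.values
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(keys=sim.keys, values=values)


@dataclass(frozen=True)
class Ordination:
    """PCoA result: coordinates (samples x axes) for the non-negative eigenvalues."""

    keys: tuple[SampleKey, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # per retained axis

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(
            self.coordinates, index=[k.label for k in self.keys], columns=cols
        )


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical metric MDS: double-centre -D^2/2, eigendecompose, scale by sqrt(eig).

    Axes with negative eigenvalues are dropped (and logged); their
    eigenvalues are still reported for diagnostics.
    """
    n = len(dm.keys)
    if n_axes is None:
        n_axes = n - 1
    if not 0 < n_axes < n:
        raise ValueError(f"n_axes must be in [1, {n - 1}], got {n_axes}")
    d2 = dm.values ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # numerical noise around zero is clipped before the positivity cut
    eigvals[np.abs(eigvals) < 1e-10] = 0.0
    n_neg = int((eigvals < 0).sum())
    if n_neg:
        logger.info("dropping %d negative-eigenvalue axes from the ordination", n_neg)
    positive = eigvals > 0
    retained = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :retained] * np.sqrt(eigvals[:retained])
    total = eigvals[positive].sum()
    proportion = eigvals[:retained] / total if total > 0 else np.zeros(retained)
    return Ordination(
        keys=dm.keys,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


def write_ordination(ord_: Ordination, coords_path: str | Path, json_path: str | Path) -> None:
    ord_.to_dataframe().to_csv(coords_path, sep="\t")
    payload = {
        "eigenvalues": [float(x) for x in ord_.eigenvalues],
        "proportion_explained": [float(x) for x in ord_.proportion_explained],
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U. Exact enumeration for small tie-free groups,
    tie-corrected normal approximation otherwise. Returns (U of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def household_distance_comparison(similarity: DistanceMatrix) -> dict:
    """Compare Sorensen similarities within vs between households.

    Within: every cross-subject sample pair inside a two-person household
    (all timepoint combinations). Between: cross-subject pairs spanning two
    households. Same-subject pairs are excluded from both groups. Returns
    group means with standard errors and the two-sided Mann-Whitney U test.
    """
    within, between = [], []
    keys = similarity.keys
    for i, a in enumerate(keys):
        for j in range(i + 1, len(keys)):
            b = keys[j]
            if a.subject_id == b.subject_id:
                continue
            value = float(similarity.values[i, j])
            if a.household_id == b.household_id:
                within.append(value)
            else:
                between.append(value)
    if not within or not between:
        raise ValueError("need at least one within-household and one between-household pair")
    u, p = mann_whitney_u(within, between)
    within = np.array(within)
    between = np.array(between)
    return {
        "within_mean": float(within.mean()),
        "within_se": float(within.std(ddof=1) / np.sqrt(len(within))) if len(within) > 1 else 0.0,
        "between_mean": float(between.mean()),
        "between_se": float(between.std(ddof=1) / np.sqrt(len(between))) if len(between) > 1 else 0.0,
        "n_within": int(len(within)),
        "n_between": int(len(between)),
        "U": u,
        "p": p,
    }
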
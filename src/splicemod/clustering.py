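"""Events x comparisons ΔPSI matrix and k-means response clustering.

Rows are the union of events significant in at least one comparison; a
cell holds that comparison's inclusion-level difference when the event was
detected (passed coverage) there and is masked otherwise.  Masked cells
are imputed with a neutral ΔPSI of 0 before k-means, which operates on the
raw ΔPSI scale (all columns share the [-1, 1] scale, so no standardization).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .events import ComparisonSet, EXCLUDED, INCLUDED


class EmptyMatrixError(ValueError):
    """No event qualified for the matrix."""


@dataclass
class DeltaPsiMatrix:
    event_keys: list[str]
    comparison_labels: list[str]
    values: np.ndarray          # (n_events, n_comparisons), 0.0 where masked
    mask: np.ndarray            # True = not detected with sufficient reads
    annotations: pd.DataFrame   # index=key, columns: event_type, novel_ss

    def __post_init__(self) -> None:
        n, m = len(self.event_keys), len(self.comparison_labels)
        if self.values.shape != (n, m) or self.mask.shape != (n, m):
            raise ValueError("matrix shapes disagree")
        if n and not np.all((~self.mask).sum(axis=1) >= 1):
            raise ValueError("every row must have at least one unmasked cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def imputed(self, imputation_value: float = 0.0) -> np.ndarray:
        """Matrix with masked cells replaced; unmasked cells untouched."""
        out = self.values.copy()
        out[self.mask] = imputation_value
        return out


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    k: int
    seed: int
    imputation_value: float

    def members(self, cluster_id: int) -> list[str]:
        return [key for key, c in self.labels.items() if c == cluster_id]


@dataclass
class ClusterSummary:
    cluster_id: int
    size: int
    novel_fraction: float
    coherent: bool
    direction: str | None            # included/excluded when coherent
    deltas: dict[str, list[float]]   # per-comparison unmasked ΔPSI values
    mean_delta: float


def build_matrix(
    significant: Mapping[str, ComparisonSet],
    detected: Mapping[str, ComparisonSet],
) -> DeltaPsiMatrix:
    """Assemble the ΔPSI matrix over events significant in >= 1 comparison.

    ``significant`` holds the significance-called sets and ``detected`` the
    coverage-passing universes, keyed by the same comparison labels in the
    same order.
    """
    if set(significant) != set(detected):
        raise ValueError("significant and detected comparisons must share labels")
    labels = list(significant)
    keys = sorted(set().union(*(cs.keys() for cs in significant.values())))
    if not keys:
        raise EmptyMatrixError("no event is significant in any comparison")
    n, m = len(keys), len(labels)
    values = np.zeros((n, m))
    mask = np.ones((n, m), dtype=bool)
    ann: dict[str, tuple[str, bool]] = {}
    for j, label in enumerate(labels):
        events = detected[label].events
        for i, key in enumerate(keys):
            q = events.get(key)
            if q is None or q.inc_level_difference is None:
                continue
            values[i, j] = q.inc_level_difference
            mask[i, j] = False
            ann[key] = (q.event.event_type, q.event.novel_ss)
    annotations = pd.DataFrame(
        [ann[key] for key in keys], index=keys, columns=["event_type", "novel_ss"]
    )
    return DeltaPsiMatrix(
        event_keys=keys, comparison_labels=labels,
        values=values, mask=mask, annotations=annotations,
    )


def cluster_events(
    m: DeltaPsiMatrix,
    k: int = 10,
    seed: int = 42,
    n_init: int = 10,
    max_iter: int = 300,
    imputation_value: float = 0.0,
) -> ClusterAssignment:
    """Partition events by k-means on the (imputed) ΔPSI matrix.

    Random centroid initialization with the stated restarts and iteration
    cap; identical inputs and seed give identical labels.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(m.event_keys) < k:
        raise ValueError(
            f"only {len(m.event_keys)} events for k={k}; choose a smaller k"
        )
    km = KMeans(
        n_clusters=k, init="random", n_init=n_init, max_iter=max_iter,
        random_state=seed,
    )
    labels = km.fit_predict(m.imputed(imputation_value))
    return ClusterAssignment(
        labels={key: int(c) for key, c in zip(m.event_keys, labels)},
        k=k, seed=seed, imputation_value=imputation_value,
    )


def cluster_summary(
    m: DeltaPsiMatrix, ca: ClusterAssignment, cluster_id: int
) -> ClusterSummary:
    """Distributions, novel-splice-site fraction and direction coherence of
    one cluster (violin-plot/pie-chart numbers)."""
    members = ca.members(cluster_id)
    if not members:
        raise ValueError(f"unknown or empty cluster {cluster_id}")
    index = {key: i for i, key in enumerate(m.event_keys)}
    rows = [index[key] for key in members]
    deltas: dict[str, list[float]] = {}
    values: list[float] = []
    for j, label in enumerate(m.comparison_labels):
        col = [
            float(m.values[i, j]) for i in rows if not m.mask[i, j]
        ]
        deltas[label] = col
        values.extend(col)
    arr = np.array(values)
    coherent = bool(np.all(arr < 0) or np.all(arr > 0))
    direction = None
    if coherent and arr.size:
        direction = INCLUDED if arr[0] < 0 else EXCLUDED
    novel = m.annotations.loc[members, "novel_ss"].astype(bool)
    return ClusterSummary(
        cluster_id=cluster_id,
        size=len(members),
        novel_fraction=float(novel.mean()),
        coherent=coherent,
        direction=direction,
        deltas=deltas,
        mean_delta=float(arr.mean()) if arr.size else float("nan"),
    )


def export_matrix(
    m: DeltaPsiMatrix, ca: ClusterAssignment | None, path
) -> None:
    """Heatmap-ready export: rows sorted by cluster then mean ΔPSI; masked
    cells printed as NA."""
    means = np.where(m.mask, np.nan, m.values)
    with np.errstate(invalid="ignore"):
        row_mean = np.nanmean(means, axis=1)
    order = range(len(m.event_keys))
    if ca is not None:
        order = sorted(
            order, key=lambda i: (ca.labels[m.event_keys[i]], row_mean[i])
        )
    else:
        order = sorted(order, key=lambda i: row_mean[i])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["key", *m.comparison_labels, "cluster", "novel_ss"]
        )
        for i in order:
            key = m.event_keys[i]
            cells = [
                "NA" if m.mask[i, j] else f"{m.values[i, j]:.4f}"
                for j in range(len(m.comparison_labels))
            ]
            writer.writerow(
                [key, *cells,
                 ca.labels[key] if ca is not None else "NA",
                 int(bool(m.annotations.loc[key, "novel_ss"]))]
            )
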
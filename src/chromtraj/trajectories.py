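"""Temporal open/closed trajectory classification and transient clustering.

A region's per-stage signal is binarised against the FPR-calibrated threshold
(strictly above = open). The boolean trajectory over the ordered stages is
then classed:

* PO    — open at every stage (permanently open)
* NEVER — closed at every stage
* CO    — exactly one closed->open transition and no reversion
* OC    — exactly one open->closed transition and no reversion
* TRANSIENT — anything else (status switches more than once)

CO/OC carry the switch stage (the first stage in the new state). Per-stage
CO/OC counts are cumulative by switch stage, so they increase monotonically
over the course, while the PO count is constant. Transient regions are soft
clustered with fuzzy c-means on per-condition z-standardised trajectories and
the resulting cluster mean shapes are categorised (shared/condition-specific
up, loss, transient).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .atlas import OpenThreshold, SignalMatrix

CLASSES = ("PO", "CO", "OC", "NEVER", "TRANSIENT")
CLUSTER_CATEGORIES = (
    "shared transient", "shared loss", "shared up",
    "naive transient", "naive up", "primed transient", "primed up",
    "unclassified",
)


@dataclass(frozen=True)
class TrajectoryCall:
    region_id: str
    condition: str
    klass: str
    switch_stage: str | None
    calls: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if (self.switch_stage is not None) != (self.klass in ("CO", "OC")):
            raise ValueError("switch_stage defined iff class is CO or OC")


def binarize(matrix: SignalMatrix, threshold: OpenThreshold) -> pd.DataFrame:
    """Boolean open calls: value strictly above the threshold."""
    if threshold.log_base is not None and threshold.log_base != matrix.log_base:
        raise ValueError(
            f"threshold log base {threshold.log_base} does not match "
            f"matrix log base {matrix.log_base}"
        )
    return matrix.values > threshold.value


def classify(calls: Sequence[bool], stages: Sequence[str], region_id: str = "",
             condition: str = "") -> TrajectoryCall:
    """Class one boolean trajectory over >= 3 ordered stages."""
    if len(calls) < 3:
        raise ValueError("need >= 3 stages to classify a trajectory")
    if len(calls) != len(stages):
        raise ValueError("calls and stages length mismatch")
    arr = [bool(c) for c in calls]
    n_up = sum(1 for a, b in zip(arr, arr[1:]) if not a and b)   # closed->open
    n_down = sum(1 for a, b in zip(arr, arr[1:]) if a and not b)  # open->closed
    switch: str | None = None
    if all(arr):
        klass = "PO"
    elif not any(arr):
        klass = "NEVER"
    elif n_up == 1 and n_down == 0:
        klass = "CO"
        switch = stages[arr.index(True)]
    elif n_down == 1 and n_up == 0:
        klass = "OC"
        switch = stages[arr.index(False)]
    else:
        klass = "TRANSIENT"
    return TrajectoryCall(region_id=region_id, condition=condition, klass=klass,
                          switch_stage=switch, calls=tuple(arr))


def classify_matrix(calls: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Classify every region of a boolean call matrix.

    Returns a frame indexed by region_id with columns class, switch_stage and
    the per-stage boolean calls.
    """
    stages = list(calls.columns)
    records = []
    for region_id, row in zip(calls.index, calls.to_numpy()):
        tc = classify(row, stages, region_id=region_id, condition=condition)
        records.append((region_id, condition, tc.klass, tc.switch_stage, *tc.calls))
    return pd.DataFrame(
        records, columns=["region_id", "condition", "class", "switch_stage", *stages]
    ).set_index("region_id")


def class_counts(traj: pd.DataFrame) -> dict[str, int]:
    counts = traj["class"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in CLASSES}


def stage_counts(traj: pd.DataFrame, stages: Sequence[str]) -> pd.DataFrame:
    """Cumulative PO/CO/OC tallies per stage.

    CO (OC) at stage s counts regions whose switch happened at or before s;
    the PO count is flat.
    """
    order = {s: i for i, s in enumerate(stages)}
    n_po = int((traj["class"] == "PO").sum())
    out = pd.DataFrame(0, index=list(stages), columns=["PO", "CO", "OC"])
    out["PO"] = n_po
    for klass in ("CO", "OC"):
        sw = traj.loc[traj["class"] == klass, "switch_stage"].map(order)
        for s in stages:
            out.loc[s, klass] = int((sw <= order[s]).sum())
    return out


def co_occurrence(traj_a: pd.DataFrame, traj_b: pd.DataFrame, klass: str,
                  stages: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Joint switch-stage histogram over regions of one class in both conditions.

    Entry (i, j) counts regions switching at stage i in condition A and stage
    j in condition B. Regions of the class in both conditions but lacking a
    switch stage in either are excluded; their count is returned alongside.
    """
    if klass not in ("CO", "OC"):
        raise ValueError("co-occurrence is defined for CO or OC regions")
    shared = traj_a.index[(traj_a["class"] == klass)].intersection(
        traj_b.index[(traj_b["class"] == klass)])
    mat = pd.DataFrame(0, index=list(stages), columns=list(stages))
    excluded = 0
    for rid in shared:
        sa = traj_a.loc[rid, "switch_stage"]
        sb = traj_b.loc[rid, "switch_stage"]
        if sa is None or sb is None:
            excluded += 1
            continue
        mat.loc[sa, sb] += 1
    return mat, excluded


# ---------------------------------------------------------------------------
# fuzzy c-means over transient trajectories


@dataclass
class FuzzyClusters:
    """Fuzzy c-means solution over z-standardised transient trajectories."""

    membership: pd.DataFrame           # region x cluster, rows sum to 1
    centers: np.ndarray                # cluster x (stages * conditions), z units
    conditions: list[str]
    stages: list[str]
    m: float
    n_iter: int
    converged: bool

    @property
    def c(self) -> int:
        return self.membership.shape[1]

    def hard_assignment(self) -> pd.Series:
        return pd.Series(self.membership.to_numpy().argmax(axis=1),
                         index=self.membership.index)

    def center_trajectory(self, cluster: int, condition: str) -> np.ndarray:
        """Cluster mean shape for one condition, in stage order (z units)."""
        k = self.conditions.index(condition)
        n = len(self.stages)
        return self.centers[cluster, k * n:(k + 1) * n]


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-region standardisation across stages; zero-variance rows become 0."""
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)


def fuzzy_cmeans(data: np.ndarray, c: int, m: float = 2.0,
                 seed: int | np.random.Generator = 0, tol: float = 1e-6,
                 max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Bezdek fuzzy c-means with Euclidean distance.

    Returns (membership U [n x c], centers [c x p], n_iter, converged).
    Memberships are initialised uniformly at random (Dirichlet-like, seeded)
    and the alternating update runs to tol on max |dU| or max_iter.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    if c < 1:
        raise ValueError("c must be >= 1")
    if n < c:
        raise ValueError(f"fewer observations ({n}) than clusters ({c})")
    if c == 1:
        return np.ones((n, 1)), x.mean(axis=0, keepdims=True), 0, True
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    exponent = 2.0 / (m - 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u ** m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = cdist(x, centers, metric="sqeuclidean")
        zero = d2 <= 1e-300
        d2c = np.where(zero, 1.0, d2)
        inv = (1.0 / d2c) ** (exponent / 2.0)
        u_new = inv / inv.sum(axis=1, keepdims=True)
        # points coincident with a center get full membership there
        hit = zero.any(axis=1)
        if hit.any():
            u_new[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            converged = True
            break
    um = u ** m
    centers = (um.T @ x) / um.sum(axis=0)[:, None]
    return u, centers, it, converged


def cluster_transient(signal_by_condition: Mapping[str, pd.DataFrame], c: int = 10,
                      m: float = 2.0, seed: int | np.random.Generator = 0,
                      tol: float = 1e-6, max_iter: int = 500) -> FuzzyClusters:
    """Soft-cluster transient regions on concatenated per-condition z shapes.

    ``signal_by_condition`` maps condition -> (region x stage) signal frame
    restricted to TRANSIENT regions; frames must share the region index. Each
    frame is z-standardised per region, then the conditions are concatenated
    column-wise before clustering, mirroring the Mfuzz convention of
    standardising expression profiles before soft clustering.
    """
    conditions = list(signal_by_condition)
    if not conditions:
        raise ValueError("no conditions supplied")
    index = signal_by_condition[conditions[0]].index
    stages = list(signal_by_condition[conditions[0]].columns)
    blocks = []
    for cond in conditions:
        df = signal_by_condition[cond]
        if not df.index.equals(index) or list(df.columns) != stages:
            raise ValueError("condition frames must share regions and stages")
        blocks.append(zscore_rows(df).to_numpy())
    data = np.hstack(blocks)
    u, centers, n_iter, converged = fuzzy_cmeans(data, c=c, m=m, seed=seed,
                                                 tol=tol, max_iter=max_iter)
    membership = pd.DataFrame(u, index=index,
                              columns=[f"C{i + 1}" for i in range(u.shape[1])])
    return FuzzyClusters(membership=membership, centers=centers,
                         conditions=conditions, stages=stages, m=m,
                         n_iter=n_iter, converged=converged)


def _shape_label(y: np.ndarray, z_threshold: float, spearman_min: float,
                 flat_span: float) -> str:
    """Label one cluster-mean trajectory: up / loss / transient / flat / other."""
    if y.max() - y.min() < flat_span:
        return "flat"
    rho = spearmanr(y, np.arange(len(y))).statistic
    if y[-1] >= z_threshold and rho >= spearman_min:
        return "up"
    if y[-1] <= -z_threshold and rho <= -spearman_min:
        return "loss"
    if len(y) > 2:
        interior = y[1:-1]
        peak = float(interior.max())
        dip = float(interior.min())
        if peak - y[0] >= z_threshold and peak - y[-1] >= z_threshold:
            return "transient"
        if y[0] - dip >= z_threshold and y[-1] - dip >= z_threshold:
            return "transient"
    return "other"


def categorize_clusters(clusters: FuzzyClusters, z_threshold: float = 0.5,
                        spearman_min: float = 0.6,
                        flat_span: float = 0.5) -> dict[str, str]:
    """Map each cluster to a shared / condition-specific category.

    Per condition, the cluster mean shape is labelled "up" (final z at least
    +z_threshold with a positive monotone trend), "loss" (mirrored), or
    "transient" (an interior extremum clears both endpoints by z_threshold);
    a span below flat_span is "flat". Both conditions agreeing gives a shared
    category; one labelled with the other flat gives a condition-specific
    category where the enum defines one; everything else is unclassified.
    """
    out: dict[str, str] = {}
    conds = clusters.conditions
    for j, name in enumerate(clusters.membership.columns):
        labels = {
            cond: _shape_label(clusters.center_trajectory(j, cond),
                               z_threshold, spearman_min, flat_span)
            for cond in conds
        }
        values = list(labels.values())
        category = "unclassified"
        if len(set(values)) == 1 and values[0] in ("up", "loss", "transient"):
            category = f"shared {values[0]}"
        else:
            for cond in conds:
                others = [labels[c2] for c2 in conds if c2 != cond]
                if labels[cond] in ("up", "transient") and all(o == "flat" for o in others):
                    candidate = f"{cond} {labels[cond]}"
                    if candidate in CLUSTER_CATEGORIES:
                        category = candidate
                    break
        out[name] = category
    return out
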
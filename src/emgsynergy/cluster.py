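"""Cross-subject synergy clustering with mutual-assignment model selection.

Synergies from all subjects, tasks and styles (one body side at a time) are
pooled as rows of a matrix and clustered with k-means.  Model selection is
two-level:

* at fixed k, k-means is repeated ``n_rep`` times (default 20) and the
  repetition with the highest mean silhouette wins;
* the cluster count is the smallest k at which fewer than ``ma_threshold``
  percent (default 10%) of trials have two or more of their synergies
  assigned to the same cluster ("mutual assignment", MA); this inner
  selection is repeated ``n_outer`` times (default 200) and the modal k is
  adopted.

``centroid_sign_profile`` tests, per cluster and channel, whether the
weight median across member synergies differs from zero (Wilcoxon
signed-rank), distinguishing consistently positive, consistently negative
(inhibitory) and indeterminate-sign channels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .seeding import derive_seed

__all__ = [
    "SynergyPool",
    "ClusterSolution",
    "kmeans_best_of",
    "mutual_assignment_pct",
    "select_cluster_number",
    "centroid_sign_profile",
    "reclassify_by_style",
]

PROVENANCE_COLS = ["subject", "side", "task", "style", "trial_id", "synergy_index"]


@dataclass
class SynergyPool:
    """Pooled synergies (rows) with per-row provenance.

    ``provenance`` must carry the columns in :data:`PROVENANCE_COLS`;
    ``trial_id`` groups rows that came from one extracted synergy set.
    """

    vectors: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (instances x channels)")
        if len(self.provenance) != self.vectors.shape[0]:
            raise ValueError("provenance length does not match vectors")
        missing = [c for c in PROVENANCE_COLS if c not in self.provenance.columns]
        if missing:
            raise ValueError(f"provenance missing columns {missing}")
        sides = set(self.provenance["side"])
        if len(sides) > 1:
            raise ValueError(
                f"pool mixes sides {sorted(sides)}; cluster each side separately"
            )
        self.provenance = self.provenance.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]


@dataclass
class ClusterSolution:
    k: int
    assignment: np.ndarray  # labels in 1..k
    centroids: np.ndarray
    mean_silhouette: float
    ma_pct: float | None = None
    seed: int | None = None


def kmeans_best_of(
    pool: SynergyPool, k: int, n_rep: int = 20, seed: int = 0
) -> ClusterSolution:
    """Best of ``n_rep`` k-means runs by mean silhouette (Euclidean)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k >= pool.n_rows:
        raise ValueError(f"k={k} must be smaller than the pool size {pool.n_rows}")
    best = None
    for rep in range(n_rep):
        sub = derive_seed(seed, "kmeans", k, rep)
        km = KMeans(n_clusters=k, n_init=1, random_state=sub).fit(pool.vectors)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            sil = -1.0
        else:
            sil = float(silhouette_score(pool.vectors, labels))
        if best is None or sil > best[0]:
            best = (sil, labels, km.cluster_centers_)
    sil, labels, centroids = best
    sol = ClusterSolution(
        k=k, assignment=labels + 1, centroids=centroids,
        mean_silhouette=sil, seed=seed,
    )
    sol.ma_pct = mutual_assignment_pct(sol, pool)
    return sol


def mutual_assignment_pct(solution: ClusterSolution, pool: SynergyPool) -> float:
    """Percentage of trials with >= 2 synergies sharing a cluster label."""
    labels = np.asarray(solution.assignment)
    if labels.shape[0] != pool.n_rows:
        raise ValueError("assignment does not cover the pool")
    df = pd.DataFrame({"trial_id": pool.provenance["trial_id"], "label": labels})
    has_ma = df.groupby("trial_id")["label"].apply(lambda s: s.duplicated().any())
    return 100.0 * float(has_ma.mean())


def select_cluster_number(
    pool: SynergyPool,
    k_range: Sequence[int] | None = None,
    ma_threshold: float = 10.0,
    n_outer: int = 200,
    n_rep: int = 20,
    seed: int = 0,
) -> tuple[int, dict]:
    """Modal minimum-k satisfying MA% < threshold over repeated selections.

    Per outer repetition, k ascends through ``k_range`` and the first k with
    MA% below the threshold is recorded (the largest k, flagged, if none
    qualifies).  The modal selection across repetitions is returned (ties
    break toward the smaller k) together with a trace of all selections.
    """
    if k_range is None:
        k_range = range(2, min(25, pool.n_rows - 1) + 1)
    k_range = list(k_range)
    if sorted(k_range) != k_range:
        raise ValueError("k_range must be ascending")
    selections, flags, ma_traces = [], [], []
    for r in range(n_outer):
        sub = derive_seed(seed, "outer", r)
        chosen, flagged = None, True
        ma_by_k = {}
        for k in k_range:
            sol = kmeans_best_of(pool, k, n_rep=n_rep, seed=derive_seed(sub, k))
            ma_by_k[k] = sol.ma_pct
            if sol.ma_pct < ma_threshold:
                chosen, flagged = k, False
                break
        if chosen is None:
            chosen = k_range[-1]
        selections.append(chosen)
        flags.append(flagged)
        ma_traces.append(ma_by_k)
    if all(flags):
        raise RuntimeError(
            f"no k in {k_range} reached MA% < {ma_threshold} in any of "
            f"{n_outer} repetitions"
        )
    counts = Counter(selections)
    modal_k = min(counts, key=lambda k: (-counts[k], k))
    trace = {
        "selections": selections,
        "histogram": dict(sorted(counts.items())),
        "flagged": flags,
        "ma_by_k": ma_traces,
        "k_range": k_range,
        "ma_threshold": ma_threshold,
    }
    return modal_k, trace


def centroid_sign_profile(
    solution: ClusterSolution, pool: SynergyPool, alpha: float = 0.05
) -> pd.DataFrame:
    """Per (cluster, channel): median weight, signed-rank p against zero
    median, and a significance mask.

    Channels failing the test are "indeterminate sign"; clusters of size 1
    report an unavailable p and are masked out.
    """
    rows = []
    labels = np.asarray(solution.assignment)
    n_ch = pool.vectors.shape[1]
    for c in range(1, solution.k + 1):
        members = pool.vectors[labels == c]
        for ch in range(n_ch):
            w = members[:, ch]
            med = float(np.median(w)) if w.size else np.nan
            if w.size < 2 or np.all(w == 0):
                p = np.nan
            else:
                try:
                    p = float(sps.wilcoxon(w, zero_method="wilcox").pvalue)
                except ValueError:  # all differences zero after dropping
                    p = np.nan
            sig = bool(p < alpha) if np.isfinite(p) else False
            rows.append(
                {
                    "cluster": c, "channel": ch, "n_members": int(w.size),
                    "median_weight": med, "p_value": p, "significant": sig,
                    "sign": (np.sign(med) if sig else 0.0),
                }
            )
    return pd.DataFrame(rows)


def reclassify_by_style(
    solution: ClusterSolution, pool: SynergyPool
) -> tuple[pd.DataFrame, dict]:
    """Partition pooled synergies by (cluster, style).

    Returns a cluster x style count table (all styles present, zero-filled)
    and a membership mapping (cluster, style) -> row indices.
    """
    labels = np.asarray(solution.assignment)
    styles = sorted(set(pool.provenance["style"]))
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, solution.k + 1, name="cluster"),
        columns=pd.Index(styles, name="style"),
    )
    membership: dict = {
        (c, s): [] for c in range(1, solution.k + 1) for s in styles
    }
    for i, (lab, style) in enumerate(zip(labels, pool.provenance["style"])):
        counts.loc[lab, style] += 1
        membership[(int(lab), style)].append(i)
    return counts, membership
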
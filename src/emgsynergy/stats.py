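"""Statistics on inhibitory synergy components.

Two levels of analysis:

* **Proportion of inhibitory components** per synergy,
  ``sum(|negative weights|) / sum(|all weights|)``: compared across age or
  expertise groups with the Kruskal-Wallis test (robust to unbalanced
  groups) and across tempo/force styles with the Wilcoxon signed-rank test
  on matched pairs (the Anderson-Darling normality check is recorded but,
  matching practice, never gates the rank test).

* **Component-level modulation**: within each synergy cluster, channels
  whose mean weight is negative in at least one of the compared styles are
  "inhibitory components"; their paired weight differences (fast - slow,
  or soft - loud) are tested per channel with the signed-rank test.
  Clusters with fewer than ``min_pairs`` (default 10) matched pairs are
  excluded as uncommon.

Raw p-values are reported (no multiple-testing correction by default, an
optional Benjamini-Hochberg switch is provided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ProportionRecord",
    "PairedContrast",
    "inhibitory_proportion",
    "group_compare",
    "build_paired_contrast",
    "paired_style_test",
    "find_inhibitory_channels",
    "component_modulation",
]

logger = logging.getLogger(__name__)

RECORD_COLS = [
    "cluster", "subject", "side", "task", "style",
    "age_group", "expertise", "proportion",
]

_FACTOR_LEVELS = {
    # factor -> (style-string position, level_a, level_b); diff = a - b
    "tempo": (0, "F", "S"),  # fast - slow
    "force": (1, "S", "L"),  # soft - loud
}


@dataclass
class ProportionRecord:
    """Inhibitory proportion of one synergy instance with its labels."""

    cluster: int
    subject: str
    side: str
    task: str
    style: str
    age_group: str
    expertise: str
    proportion: float


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = [c for c in RECORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# the proportion statistic
# ---------------------------------------------------------------------------

def inhibitory_proportion(w) -> float:
    """``sum(|w_i| for w_i < 0) / sum(|w_i|)`` -- scale invariant, in [0,1]."""
    w = np.asarray(w, dtype=float)
    total = np.abs(w).sum()
    if total == 0:
        raise ValueError("all-zero weight vector has no defined proportion")
    return float(np.abs(w[w < 0]).sum() / total)


# ---------------------------------------------------------------------------
# group comparisons (age / expertise)
# ---------------------------------------------------------------------------

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = np.isfinite(p).sum()
    order = np.argsort(np.where(np.isfinite(p), p, np.inf))
    adj = np.full_like(p, np.nan)
    prev = 1.0
    ranked = [(i, p[i]) for i in order if np.isfinite(p[i])]
    for rank, (i, pv) in reversed(list(enumerate(ranked, start=1))):
        prev = min(prev, pv * n / rank)
        adj[i] = prev
    return adj


def group_compare(
    records,
    grouping: str,
    alpha: float = 0.01,
    aggregate_subjects: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of inhibitory proportions across groups.

    One test per (side, cluster).  ``grouping`` is ``'age_group'`` or
    ``'expertise'``.  With ``aggregate_subjects=True`` each subject
    contributes its mean proportion instead of every synergy instance.
    Cells with fewer than two nonempty groups are skipped; singleton groups
    are run but flagged with a caveat.
    """
    if grouping not in ("age_group", "expertise"):
        raise ValueError("grouping must be 'age_group' or 'expertise'")
    df = records_to_frame(records)
    rows = []
    for (side, cluster), cell in df.groupby(["side", "cluster"]):
        if aggregate_subjects:
            cell = (
                cell.groupby(["subject", grouping], as_index=False)["proportion"]
                .mean()
            )
        groups = {
            g: sub["proportion"].to_numpy()
            for g, sub in cell.groupby(grouping)
            if len(sub) > 0
        }
        if len(groups) < 2:
            logger.info(
                "skipping (%s, cluster %s): fewer than two nonempty %s groups",
                side, cluster, grouping,
            )
            continue
        singleton = any(len(v) == 1 for v in groups.values())
        if singleton:
            logger.warning(
                "(%s, cluster %s): a %s group has a single observation; the "
                "Kruskal-Wallis result should be read with caution",
                side, cluster, grouping,
            )
        values = list(groups.values())
        if len(np.unique(np.concatenate(values))) == 1:
            H, p = 0.0, 1.0  # no rank variation at all
        else:
            try:
                H, p = sps.kruskal(*values)
            except ValueError:
                H, p = 0.0, 1.0
            if not np.isfinite(p):
                H, p = 0.0, 1.0
        rows.append(
            {
                "side": side, "cluster": cluster, "grouping": grouping,
                "H": float(H), "p_value": float(p),
                "n_per_group": {g: int(len(v)) for g, v in groups.items()},
                "median_per_group": {g: float(np.median(v))
                                     for g, v in groups.items()},
                "singleton_group": singleton,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if adjust:
        out["p_adjusted"] = _bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


# ---------------------------------------------------------------------------
# paired style contrasts
# ---------------------------------------------------------------------------

@dataclass
class PairedContrast:
    """Matched pairs differing only in the contrasted factor level.

    Sign convention of ``diff``: tempo = fast - slow; force = soft - loud.
    """

    factor: str
    pairs: pd.DataFrame  # columns: side, cluster, subject, task, other_level,
    #                               value_a, value_b, diff
    n_unmatched: int


def _split_style(style: str, factor: str) -> tuple[str, str]:
    """-> (level of the contrasted factor, level of the other factor)."""
    pos, _, _ = _FACTOR_LEVELS[factor]
    return style[pos], style[1 - pos]


def build_paired_contrast(records, factor: str) -> PairedContrast:
    """Pair proportion records across the two levels of tempo or force.

    Records are averaged within each (side, cluster, subject, task,
    other-factor level) cell first (mutual-assignment duplicates), then
    cells present at both levels form pairs; unmatched cells are counted.
    """
    if factor not in _FACTOR_LEVELS:
        raise ValueError("factor must be 'tempo' or 'force'")
    pos, lev_a, lev_b = _FACTOR_LEVELS[factor]
    df = records_to_frame(records)
    df = df.assign(
        _level=df["style"].str[pos],
        other_level=df["style"].str[1 - pos],
    )
    cell_means = (
        df.groupby(["side", "cluster", "subject", "task", "other_level", "_level"])
        ["proportion"].mean().unstack("_level")
    )
    have_a = lev_a in cell_means.columns
    have_b = lev_b in cell_means.columns
    if have_a and have_b:
        matched = cell_means.dropna(subset=[lev_a, lev_b])
    else:
        matched = cell_means.iloc[0:0]
    n_unmatched = len(cell_means) - len(matched)
    pairs = matched.reset_index().rename(
        columns={lev_a: "value_a", lev_b: "value_b"}
    )
    if "value_a" not in pairs.columns:
        pairs["value_a"] = np.nan
    if "value_b" not in pairs.columns:
        pairs["value_b"] = np.nan
    pairs["diff"] = pairs["value_a"] - pairs["value_b"]
    keep = ["side", "cluster", "subject", "task", "other_level",
            "value_a", "value_b", "diff"]
    return PairedContrast(factor, pairs[keep], int(n_unmatched))


def _wilcoxon_paired(diffs: np.ndarray) -> tuple[float, int]:
    """Signed-rank p on paired differences (zeros dropped; exact for
    n <= 25 without ties, normal approximation with continuity correction
    otherwise).  Returns (p, n_nonzero)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 2:
        return np.nan, n
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       method=method)
    return float(res.pvalue), n


def _anderson_normal(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    if x.size < 8 or np.std(x) == 0:
        return {"statistic": np.nan, "normal": None}
    try:
        res = sps.anderson(x, dist="norm", method="interpolate")
        normal = bool(res.pvalue > 0.05)
    except TypeError:  # older scipy without the method parameter
        res = sps.anderson(x, dist="norm")
        idx = list(res.significance_level).index(5.0)
        normal = bool(res.statistic < float(res.critical_values[idx]))
    return {"statistic": float(res.statistic), "normal": normal}


def paired_style_test(contrast: PairedContrast, alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon signed-rank test of paired proportion differences per
    (side, cluster), with the Anderson-Darling normality check recorded.

    Direction labels follow the sign convention of the contrast: for tempo a
    negative median difference reads "lower at fast", for force "lower at
    soft".
    """
    level_word = {"tempo": "fast", "force": "soft"}[contrast.factor]
    rows = []
    for (side, cluster), cell in contrast.pairs.groupby(["side", "cluster"]):
        diffs = cell["diff"].to_numpy()
        if len(diffs) < 2:
            continue
        ad_a = _anderson_normal(cell["value_a"].to_numpy())
        ad_b = _anderson_normal(cell["value_b"].to_numpy())
        if np.all(diffs == 0):
            rows.append(
                {
                    "side": side, "cluster": cluster, "factor": contrast.factor,
                    "n_pairs": int(len(diffs)), "median_diff": 0.0,
                    "p_value": np.nan, "significant": False,
                    "degenerate": True, "direction": "none",
                    "ad_normal_a": ad_a["normal"], "ad_normal_b": ad_b["normal"],
                }
            )
            continue
        p, n_nonzero = _wilcoxon_paired(diffs)
        med = float(np.median(diffs))
        sig = bool(np.isfinite(p) and p < alpha)
        direction = (
            f"lower at {level_word}" if med < 0 else f"higher at {level_word}"
        ) if sig else "none"
        rows.append(
            {
                "side": side, "cluster": cluster, "factor": contrast.factor,
                "n_pairs": int(len(diffs)), "median_diff": med,
                "p_value": p, "significant": sig, "degenerate": False,
                "direction": direction,
                "ad_normal_a": ad_a["normal"], "ad_normal_b": ad_b["normal"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# component-level modulation
# ---------------------------------------------------------------------------

def find_inhibitory_channels(style_matrices: dict) -> np.ndarray:
    """Channels whose mean weight across members is < 0 in at least one of
    the compared styles.  ``style_matrices`` maps style level -> members x
    channels matrix."""
    mats = [np.asarray(m, dtype=float) for m in style_matrices.values() if len(m)]
    if not mats:
        raise ValueError("no members in any compared style")
    negative_any = np.zeros(mats[0].shape[1], dtype=bool)
    for m in mats:
        negative_any |= m.mean(axis=0) < 0
    return np.flatnonzero(negative_any)


def component_modulation(
    weights: np.ndarray,
    provenance: pd.DataFrame,
    clusters: np.ndarray,
    factor: str,
    min_pairs: int = 10,
    alpha: float = 0.05,
    channel_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(cluster, inhibitory channel) paired modulation test.

    ``weights`` are pooled synergy vectors (instances x channels) with
    ``provenance`` rows (subject, task, style, ...) and per-row ``clusters``
    labels.  Within each cluster, instances are averaged per (subject, task,
    other-factor level, contrast level) cell and paired across the contrast
    levels (tempo: fast - slow; force: soft - loud).  Clusters with fewer
    than ``min_pairs`` pairs are excluded.  Only channels identified by
    :func:`find_inhibitory_channels` on the two cell-mean matrices are
    tested; the sign label is 'less_negative' for a positive mean
    difference, 'more_negative' otherwise.
    """
    if factor not in _FACTOR_LEVELS:
        raise ValueError("factor must be 'tempo' or 'force'")
    pos, lev_a, lev_b = _FACTOR_LEVELS[factor]
    weights = np.asarray(weights, dtype=float)
    clusters = np.asarray(clusters)
    n_ch = weights.shape[1]
    names = list(channel_names) if channel_names is not None else [
        f"ch{i + 1:02d}" for i in range(n_ch)
    ]
    df = provenance.reset_index(drop=True).copy()
    df["_cluster"] = clusters
    df["_level"] = df["style"].str[pos]
    df["_other"] = df["style"].str[1 - pos]
    rows = []
    for c, cell in df.groupby("_cluster"):
        # average duplicate instances per (subject, task, other, level) cell
        cell_means: dict = {}
        for key, sub in cell.groupby(["subject", "task", "_other", "_level"]):
            cell_means[key] = weights[sub.index.to_numpy()].mean(axis=0)
        pairs_a, pairs_b = [], []
        for (subject, task, other, level), w in cell_means.items():
            if level != lev_a:
                continue
            kb = (subject, task, other, lev_b)
            if kb in cell_means:
                pairs_a.append(w)
                pairs_b.append(cell_means[kb])
        if len(pairs_a) < min_pairs:
            continue
        A = np.vstack(pairs_a)
        B = np.vstack(pairs_b)
        channels = find_inhibitory_channels({lev_a: A, lev_b: B})
        for ch in channels:
            diffs = A[:, ch] - B[:, ch]
            p, n_nonzero = _wilcoxon_paired(diffs)
            mean_diff = float(diffs.mean())
            rows.append(
                {
                    "cluster": c, "channel": int(ch), "channel_name": names[ch],
                    "factor": factor, "n_pairs": int(len(diffs)),
                    "mean_diff": mean_diff, "p_value": p,
                    "significant": bool(np.isfinite(p) and p < alpha),
                    "sign": "less_negative" if mean_diff > 0 else "more_negative",
                }
            )
    return pd.DataFrame(rows)
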
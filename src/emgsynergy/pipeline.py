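"""End-to-end orchestration, on-disk formats, and seed management.

Trials are stored as delimited text (one row per channel, full float
precision) with a JSON metadata sidecar; every stage reads the previous
stage's directory and writes its own, so the pipeline is equally usable as

    run_all(RunConfig(...))                    # one call

or stage by stage (``stage_simulate`` .. ``stage_stats``), including from
the command line.  All randomness derives from ``master_seed`` through a
hierarchical key scheme, so a rerun with the same configuration reproduces
identical outputs (the run manifest records sha256 digests to prove it).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    SynergyPool, centroid_sign_profile, kmeans_best_of, reclassify_by_style,
    select_cluster_number,
)
from .factorize import (
    FactorizationConfig, average_synergy_sets, extract_synergies,
    select_dimensionality,
)
from .preprocess import (
    EMGEnvelope, RawEMG, clean_raw, condition_envelope, make_envelope,
    segment_and_concatenate,
)
from .seeding import derive_seed
from .stats import (
    build_paired_contrast, component_modulation, group_compare,
    inhibitory_proportion, paired_style_test, records_to_frame,
)
from .synthetic import CohortConfig, StyleEffect, simulate_cohort

__all__ = [
    "RunConfig", "read_trial", "write_trial", "run_all",
    "stage_simulate", "stage_preprocess", "stage_factorize",
    "stage_cluster", "stage_stats",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # lossless float64 round trip
_SIDE_CAR_REQUIRED = ["kind", "fs", "channel_names"]


# ---------------------------------------------------------------------------
# trial serialization
# ---------------------------------------------------------------------------

def write_trial(trial, path) -> Path:
    """Write a RawEMG/EMGEnvelope as ``<path>.tsv`` + ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tsv = path.with_suffix(".tsv")
    np.savetxt(tsv, trial.data, fmt=_FLOAT_FMT, delimiter="\t")
    sidecar = {
        "kind": "envelope" if isinstance(trial, EMGEnvelope) else "raw",
        "fs": trial.fs,
        "channel_names": list(trial.channel_names),
        "meta": _jsonable(trial.meta),
    }
    if isinstance(trial, EMGEnvelope):
        sidecar["processing_log"] = _jsonable(trial.processing_log)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return tsv


def read_trial(path):
    """Read a trial written by :func:`write_trial` (path with or without
    suffix).  Raises on a missing/invalid sidecar or a channel mismatch."""
    path = Path(path)
    tsv, sidecar_path = path.with_suffix(".tsv"), path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar {sidecar_path} not found")
    sidecar = json.loads(sidecar_path.read_text())
    for f in _SIDE_CAR_REQUIRED:
        if f not in sidecar:
            raise ValueError(f"sidecar {sidecar_path} missing required field {f!r}")
    data = np.loadtxt(tsv, delimiter="\t", ndmin=2)
    names = sidecar["channel_names"]
    if data.shape[0] != len(names):
        raise ValueError(
            f"{tsv}: matrix has {data.shape[0]} rows but sidecar lists "
            f"{len(names)} channels"
        )
    if sidecar["kind"] == "raw":
        return RawEMG(data, sidecar["fs"], names, sidecar.get("meta", {}))
    return EMGEnvelope(
        data, sidecar["fs"], names, sidecar.get("meta", {}),
        sidecar.get("processing_log", []),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

REQUIRED_BLOCKS = ["cohort", "preprocess", "factorize", "cluster", "stats"]


@dataclass
class RunConfig:
    """Configuration of a full run; each stage has its own block."""

    cohort: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    factorize: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    master_seed: int = 0
    output_root: str = "emgsynergy_run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        missing = [b for b in REQUIRED_BLOCKS if b not in d]
        if missing:
            raise ValueError(f"run config missing stage block(s): {missing}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = [k for k in d if k not in known]
        if unknown:
            raise ValueError(f"unknown run config fields: {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _cohort_config(block: dict, master_seed: int) -> CohortConfig:
    block = dict(block)
    effects = [
        StyleEffect(**e) if isinstance(e, dict) else e
        for e in block.pop("style_effects", [])
    ]
    block.setdefault("seed", derive_seed(master_seed, "cohort"))
    return CohortConfig(style_effects=effects, **block)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cohort_block: dict, out_dir, master_seed: int = 0) -> dict:
    """Simulate a cohort and write its trials + ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _cohort_config(cohort_block, master_seed)
    cohort = simulate_cohort(cfg)
    paths = []
    for trial in cohort.trials:
        m = trial.meta
        name = f"{m['subject']}_{m['side']}_{m['task']}_{m['style']}_r{m['rep']}"
        write_trial(trial, out / name)
        paths.append(name)
    (out / "ground_truth.json").write_text(
        json.dumps(_jsonable(cohort.manifest), indent=1, sort_keys=True)
    )
    return {"n_trials": len(paths), "trials": paths, "dir": str(out)}


def stage_preprocess(in_dir, out_dir, block: dict | None = None) -> dict:
    """Clean raw trials (if raw), build envelopes, concatenate repetitions
    of the same (subject, side, task, style), despike and normalize."""
    block = block or {}
    in_dir, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups: dict = {}
    for sidecar in sorted(in_dir.glob("*.json")):
        if sidecar.name == "ground_truth.json":
            continue
        trial = read_trial(sidecar)
        if isinstance(trial, RawEMG):
            trial = clean_raw(
                trial,
                pli_freq=block.get("pli_freq", 50.0),
                n_harmonics=block.get("n_harmonics", 3),
                band=tuple(block.get("band", (20.0, 400.0))),
            )
            trial = make_envelope(
                trial,
                lp_cutoff=block.get("lp_cutoff", 40.0),
                smooth_window_ms=block.get("smooth_window_ms", 20.0),
            )
        m = trial.meta
        key = (m["subject"], m["side"], m["task"], m["style"])
        groups.setdefault(key, []).append(trial)
    written = []
    for key, trials in sorted(groups.items()):
        env = segment_and_concatenate(trials, max_gap_s=block.get("max_gap_s", 0.5))
        env = condition_envelope(env, spike_z=block.get("spike_z", 5.0))
        name = "_".join(key)
        write_trial(env, out / name)
        written.append(name)
    return {"n_envelopes": len(written), "envelopes": written, "dir": str(out)}


def stage_factorize(in_dir, out_dir, block: dict | None = None,
                    master_seed: int = 0) -> dict:
    """Per concatenated trial: select the dimensionality, extract the
    repeated solutions, average them, and write W/C/fit."""
    block = dict(block or {})
    fixed_M = block.pop("fixed_M", None)
    in_dir, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    for sidecar in sorted(in_dir.glob("*.json")):
        env = read_trial(sidecar)
        name = sidecar.stem
        cfg = FactorizationConfig(
            seed=derive_seed(master_seed, "factorize", name), **block
        )
        if fixed_M is None:
            M, sets = select_dimensionality(env, cfg, return_sets=True)
        else:
            M = fixed_M
            sets = extract_synergies(env, M, cfg)
        avg = average_synergy_sets(sets, env=env)
        np.savetxt(out / f"{name}.W.tsv", avg.W, fmt=_FLOAT_FMT, delimiter="\t")
        np.savetxt(out / f"{name}.C.tsv", avg.C, fmt=_FLOAT_FMT, delimiter="\t")
        info = {
            "trial": name, "M": int(M),
            "R2": float(avg.fit.R2),
            "R2_sets": [float(s.fit.R2) for s in sets],
            "init_ids": [int(s.init_id) for s in sets],
            "meta": _jsonable(env.meta),
            "channel_names": list(env.channel_names),
        }
        (out / f"{name}.fit.json").write_text(json.dumps(info, indent=1,
                                                         sort_keys=True))
        results.append(info)
    return {"n_trials": len(results), "results": results, "dir": str(out)}


def build_pools(fact_dir) -> dict:
    """Assemble per-side synergy pools from a factorization directory."""
    fact_dir = Path(fact_dir)
    rows: dict = {}
    vectors: dict = {}
    for fit_path in sorted(fact_dir.glob("*.fit.json")):
        info = json.loads(fit_path.read_text())
        W = np.loadtxt(fact_dir / f"{info['trial']}.W.tsv", delimiter="\t", ndmin=2)
        meta = info["meta"]
        side = meta["side"]
        for j in range(W.shape[1]):
            vectors.setdefault(side, []).append(W[:, j])
            rows.setdefault(side, []).append(
                {
                    "subject": meta["subject"], "side": side,
                    "task": meta["task"], "style": meta["style"],
                    "trial_id": info["trial"], "synergy_index": j,
                }
            )
    return {
        side: SynergyPool(np.vstack(vectors[side]), pd.DataFrame(rows[side]))
        for side in vectors
    }


def stage_cluster(in_dir, out_dir, block: dict | None = None,
                  master_seed: int = 0) -> dict:
    """Per side: select the cluster count, run the final clustering, write
    assignments, centroids, sign profiles and the selection trace."""
    block = block or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pools = build_pools(in_dir)
    summary = {}
    for side, pool in sorted(pools.items()):
        seed = derive_seed(master_seed, "cluster", side)
        k_range = block.get("k_range")
        if k_range is not None:
            k_range = range(int(k_range[0]), int(k_range[1]) + 1)
        modal_k, trace = select_cluster_number(
            pool,
            k_range=k_range,
            ma_threshold=block.get("ma_threshold", 10.0),
            n_outer=block.get("n_outer", 200),
            n_rep=block.get("n_rep", 20),
            seed=seed,
        )
        final = kmeans_best_of(pool, modal_k, n_rep=block.get("n_rep", 20),
                               seed=derive_seed(seed, "final"))
        assign = pool.provenance.copy()
        assign["cluster"] = final.assignment
        assign.to_csv(out / f"{side}.assignments.tsv", sep="\t", index=False)
        np.savetxt(out / f"{side}.centroids.tsv", final.centroids,
                   fmt=_FLOAT_FMT, delimiter="\t")
        np.savetxt(out / f"{side}.vectors.tsv", pool.vectors,
                   fmt=_FLOAT_FMT, delimiter="\t")
        signs = centroid_sign_profile(final, pool,
                                      alpha=block.get("sign_alpha", 0.05))
        signs.to_csv(out / f"{side}.sign_profile.tsv", sep="\t", index=False)
        counts, _ = reclassify_by_style(final, pool)
        counts.to_csv(out / f"{side}.style_counts.tsv", sep="\t")
        (out / f"{side}.selection.json").write_text(
            json.dumps(_jsonable({"modal_k": modal_k,
                                  "histogram": trace["histogram"],
                                  "ma_threshold": trace["ma_threshold"],
                                  "k_range": trace["k_range"],
                                  "mean_silhouette": final.mean_silhouette,
                                  "ma_pct": final.ma_pct}),
                       indent=1, sort_keys=True)
        )
        summary[side] = {"k": int(modal_k), "ma_pct": float(final.ma_pct),
                         "silhouette": float(final.mean_silhouette)}
    return {"sides": summary, "dir": str(out)}


def stage_stats(cluster_dir, out_dir, block: dict | None = None) -> dict:
    """Proportion statistics and component-level modulation tables."""
    block = block or {}
    cluster_dir, out = Path(cluster_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alpha_group = block.get("alpha_group", 0.01)
    alpha_style = block.get("alpha_style", 0.05)
    min_pairs = block.get("min_pairs", 10)
    records, group_tabs, style_tabs, mod_tabs = [], [], [], []
    for assign_path in sorted(cluster_dir.glob("*.assignments.tsv")):
        side = assign_path.name.split(".")[0]
        prov = pd.read_csv(assign_path, sep="\t")
        vectors = np.loadtxt(cluster_dir / f"{side}.vectors.tsv",
                             delimiter="\t", ndmin=2)
        meta_map = block.get("subject_labels", {})
        for i, row in prov.iterrows():
            labels = meta_map.get(row["subject"], {})
            records.append(
                {
                    "cluster": int(row["cluster"]), "subject": row["subject"],
                    "side": side, "task": row["task"], "style": row["style"],
                    "age_group": labels.get("age_group", "unknown"),
                    "expertise": labels.get("expertise", "unknown"),
                    "proportion": inhibitory_proportion(vectors[i]),
                }
            )
        prov_side = prov.copy()
        for factor in ("tempo", "force"):
            mod = component_modulation(
                vectors, prov_side, prov_side["cluster"].to_numpy(), factor,
                min_pairs=min_pairs, alpha=alpha_style,
            )
            if not mod.empty:
                mod.insert(0, "side", side)
                mod_tabs.append(mod)
    rec_df = records_to_frame(pd.DataFrame(records))
    rec_df.to_csv(out / "proportion_records.tsv", sep="\t", index=False)
    for grouping in ("age_group", "expertise"):
        if rec_df[grouping].nunique() > 1:
            tab = group_compare(rec_df, grouping, alpha=alpha_group,
                                aggregate_subjects=block.get(
                                    "aggregate_subjects", False))
            if not tab.empty:
                group_tabs.append(tab)
    for factor in ("tempo", "force"):
        contrast = build_paired_contrast(rec_df, factor)
        tab = paired_style_test(contrast, alpha=alpha_style)
        if not tab.empty:
            style_tabs.append(tab)
    outputs = {}
    for name, tabs in (
        ("group_tests", group_tabs), ("style_tests", style_tabs),
        ("modulation", mod_tabs),
    ):
        df = pd.concat(tabs, ignore_index=True) if tabs else pd.DataFrame()
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        outputs[name] = len(df)
    return {"tables": outputs, "n_records": len(rec_df), "dir": str(out)}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict:
    """Execute simulate -> preprocess -> factorize -> cluster -> stats.

    Returns (and writes) a manifest recording the package version, master
    seed, per-stage outputs and sha256 digests of every written file.  A
    rerun with the same configuration produces a byte-identical manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed
    stages = {}
    dirs = {name: root / name for name in
            ("trials", "envelopes", "synergies", "clusters", "stats")}
    plan = [
        ("simulate", lambda: stage_simulate(config.cohort, dirs["trials"], seed)),
        ("preprocess", lambda: stage_preprocess(dirs["trials"],
                                                dirs["envelopes"],
                                                config.preprocess)),
        ("factorize", lambda: stage_factorize(dirs["envelopes"],
                                              dirs["synergies"],
                                              config.factorize, seed)),
        ("cluster", lambda: stage_cluster(dirs["synergies"], dirs["clusters"],
                                          config.cluster, seed)),
        ("stats", lambda: stage_stats(dirs["clusters"], dirs["stats"],
                                      _stats_block(config))),
    ]
    for name, fn in plan:
        logger.info("running stage %s", name)
        try:
            stages[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    digests = {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package_version": __version__,
        "master_seed": seed,
        "stages": _jsonable(stages),
        "digests": digests,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                   sort_keys=True))
    return manifest


def _stats_block(config: RunConfig) -> dict:
    """Inject the cohort's subject labels into the stats stage block."""
    block = dict(config.stats)
    if "subject_labels" not in block:
        cfg = _cohort_config(config.cohort, config.master_seed)
        block["subject_labels"] = {
            s: {"age_group": cfg.age_groups[s], "expertise": cfg.expertise[s]}
            for s in cfg.subjects
        }
    return block
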
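"""Synthetic EMG cohort generation with ground-truth inhibitory components.

Real synergy studies record multichannel surface EMG from subjects
performing tasks under different tempo/force styles.  This module emulates
such a cohort end to end so every downstream stage (preprocessing,
factorization, clustering, statistics) can be exercised and validated
against a known ground truth:

* ``make_synergy_bank``    -- a bank of unit-norm synergy templates whose
  columns mix dominant positive muscle weights with a configurable fraction
  of smaller-magnitude negative ("inhibitory") weights.
* ``simulate_activations`` -- nonnegative, temporally smooth activation
  time courses (rectified low-pass-filtered Gaussian noise with a
  configurable duty cycle).
* ``synthesize_envelope``  -- the linear forward model ``Y = W C + noise``.
* ``synthesize_raw_emg``   -- an envelope-modulated band-limited carrier
  plus power-line interference, baseline offset and impulsive artifacts,
  to exercise the raw-EMG cleaning chain.
* ``simulate_cohort``      -- a labelled multi-subject cohort (age and
  expertise groups, five tasks, four tempo-force styles, two sides) with
  optionally planted group differences in inhibitory proportion and planted
  style-dependent weight shifts, recorded in a ground-truth manifest.

Default study conditions: 14 channels per side, 10 subjects (4 under 30,
5 between 30 and 50, 1 over 50; 4 junior / 6 senior experts), 5 tasks x
4 styles, scales repeated twice per style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, resample_poly, sosfiltfilt

from .preprocess import EMGEnvelope, RawEMG
from .seeding import derive_rng, derive_seed

__all__ = [
    "MUSCLES_14",
    "GroundTruthBank",
    "CohortConfig",
    "StyleEffect",
    "Cohort",
    "make_synergy_bank",
    "simulate_activations",
    "synthesize_envelope",
    "synthesize_raw_emg",
    "simulate_cohort",
]

#: the 14 shoulder/upper-arm + forearm muscles recorded per side
MUSCLES_14 = [
    "TrapMaj", "Infrasp", "DeltA", "DeltM", "BicLong", "TrLat",
    "BrRad", "PronTer", "FlexCR", "FlexCU", "FlexDG", "ExtCRL",
    "ExtCU", "ExtDG",
]

STYLES = ["FL", "FS", "SL", "SS"]  # (tempo, force): Fast/Slow x Loud/Soft

DEFAULT_TASKS = [
    "scale_cmaj", "scale_amaj", "arpeggio_cmaj", "piece_bach", "piece_schumann",
]


# ---------------------------------------------------------------------------
# ground-truth synergy bank
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthBank:
    """A channels x synergies template matrix with known negative entries."""

    W_true: np.ndarray
    channel_names: Sequence[str]
    inhibitory_mask: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.W_true.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.W_true.shape[1]

    def inhibitory_proportions(self) -> np.ndarray:
        """Sum(|negative|)/Sum(|all|) per column."""
        absW = np.abs(self.W_true)
        neg = np.where(self.W_true < 0, absW, 0.0)
        return neg.sum(axis=0) / absW.sum(axis=0)


def make_synergy_bank(
    n_channels: int,
    n_synergies: int,
    inhibitory_fraction: float,
    seed: int,
    channel_names: Sequence[str] | None = None,
    n_dominant: int = 4,
    dominant_range: tuple[float, float] = (0.6, 1.0),
    background_range: tuple[float, float] = (0.02, 0.10),
    neg_magnitude_range: tuple[float, float] = (0.04, 0.12),
    max_cosine: float = 0.8,
    min_pos_neg_ratio: float = 8.0,
    max_retries: int = 500,
) -> GroundTruthBank:
    """Draw a bank of unit-norm synergy templates.

    Each synergy recruits ``n_dominant`` dominant muscles (weights in
    ``dominant_range``) on top of small background weights, as real motor
    modules do; dominant channels are dealt round-robin across synergies so
    templates overlap as little as the geometry allows and stay mutually
    distinguishable.  ``round(inhibitory_fraction * n_channels)`` entries
    per column, placed among the non-dominant channels, are made strictly
    negative with magnitudes drawn smaller than the positive ones
    (inhibitory components are minor).  Banks are redrawn until all
    pairwise column cosines are below ``max_cosine``.

    Every channel's summed positive weight across the bank is additionally
    kept at least ``min_pos_neg_ratio`` times its summed negative
    magnitude.  This encodes that inhibition only modulates a muscle's
    otherwise dominant positive drive, and it keeps the linear forward
    model's negative excursions (which physical envelopes clip at zero)
    negligible relative to the signal.
    """
    if not (1 <= n_synergies <= n_channels):
        raise ValueError("need 1 <= n_synergies <= n_channels")
    if not (0 <= inhibitory_fraction < 0.5):
        raise ValueError("inhibitory_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_neg = int(round(inhibitory_fraction * n_channels))
    # dominant sets can only stay (mostly) disjoint if geometry allows
    n_dom = max(1, min(n_dominant, n_channels // n_synergies))
    for _ in range(max_retries):
        # deal channels round-robin into dominant sets, then top up
        perm = rng.permutation(n_channels)
        dom_sets = [list(perm[j::n_synergies][: n_dom]) for j in range(n_synergies)]
        for j, dom in enumerate(dom_sets):
            if len(dom) < n_dom:
                extra = rng.choice(
                    [c for c in range(n_channels) if c not in dom],
                    size=n_dom - len(dom), replace=False,
                )
                dom.extend(int(e) for e in extra)
        cols, masks = [], []
        for j in range(n_synergies):
            w = rng.uniform(*background_range, size=n_channels)
            w[dom_sets[j]] = rng.uniform(*dominant_range, size=n_dom)
            mask = np.zeros(n_channels, dtype=bool)
            if n_neg:
                candidates = [c for c in range(n_channels) if c not in dom_sets[j]]
                idx = rng.choice(candidates, size=min(n_neg, len(candidates)),
                                 replace=False)
                w[idx] = -rng.uniform(*neg_magnitude_range, size=len(idx))
                mask[idx] = True
            cols.append(w / np.linalg.norm(w))
            masks.append(mask)
        W = np.column_stack(cols)
        G = np.abs(W.T @ W)
        np.fill_diagonal(G, 0.0)
        if G.max() < max_cosine:
            break
    else:
        raise RuntimeError(
            f"could not draw {n_synergies} synergy templates with pairwise "
            f"cosine < {max_cosine} in {max_retries} retries"
        )
    if n_neg and min_pos_neg_ratio > 0:
        W = _enforce_row_dominance(W, min_pos_neg_ratio)
    return GroundTruthBank(
        W, list(channel_names or _default_names(n_channels)),
        np.column_stack(masks),
    )


def _enforce_row_dominance(W: np.ndarray, ratio: float,
                           max_passes: int = 20) -> np.ndarray:
    """Scale down negative entries until every channel's positive weight sum
    is >= ratio * its negative magnitude sum (columns re-normalized)."""
    W = W.copy()
    for _ in range(max_passes):
        pos = np.where(W > 0, W, 0.0).sum(axis=1)
        neg = np.where(W < 0, -W, 0.0).sum(axis=1)
        bad = neg > 0
        factor = np.ones_like(pos)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor[bad] = np.minimum(1.0, pos[bad] / (ratio * neg[bad]))
        if np.all(factor >= 1.0 - 1e-12):
            return W
        scale = np.where(W < 0, factor[:, None], 1.0)
        W *= scale
        W /= np.linalg.norm(W, axis=0, keepdims=True)
    raise RuntimeError(
        f"could not enforce positive/negative channel dominance {ratio}"
    )


def _default_names(n_channels: int) -> list[str]:
    if n_channels == len(MUSCLES_14):
        return list(MUSCLES_14)
    return [f"ch{i + 1:02d}" for i in range(n_channels)]


# ---------------------------------------------------------------------------
# activations and forward model
# ---------------------------------------------------------------------------

def simulate_activations(
    n_samples: int,
    n_synergies: int,
    smoothness_ms: float,
    fs: float,
    seed: int,
    shift: float = 0.0,
    clip_level: float = 3.0,
) -> np.ndarray:
    """Nonnegative smooth activation time courses (synergies x samples).

    White Gaussian noise is low-pass smoothed (Gaussian kernel with sigma =
    ``smoothness_ms`` in time), restandardized to unit variance, shifted by
    ``shift`` and rectified at zero.  ``shift`` sets the duty cycle (the
    fraction of time a synergy is recruited; 0 gives ~50%); activations
    still spend real time at zero, which is what makes the semi-nonnegative
    factorization identifiable.  Bursts saturate at ``clip_level`` above
    the shift (neural drive does not grow without bound).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_synergies, n_samples))
    sigma = smoothness_ms * fs / 1000.0
    if sigma > 0:
        x = gaussian_filter1d(x, sigma=sigma, axis=1, mode="reflect")
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x /= sd
    x = np.maximum(x + shift, 0.0)
    if clip_level is not None:
        x = np.minimum(x, clip_level + shift)
    return x


def synthesize_envelope(
    bank: GroundTruthBank,
    C: np.ndarray,
    noise_sd: float,
    seed: int,
    floor_at_zero: bool = False,
    fs: float = 100.0,
    meta: dict | None = None,
) -> EMGEnvelope:
    """Forward model ``Y = W_true @ C + Gaussian noise``.

    By default the output is NOT floored at zero, so factorization recovery
    tests see the exact linear model; ``floor_at_zero=True`` emulates
    physically rectified envelopes.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != bank.n_synergies:
        raise ValueError(
            f"coefficient matrix has {C.shape[0] if C.ndim == 2 else '?'} rows "
            f"but bank has {bank.n_synergies} synergies"
        )
    rng = np.random.default_rng(seed)
    Y = bank.W_true @ C
    if noise_sd:
        Y = Y + noise_sd * rng.standard_normal(Y.shape)
    if floor_at_zero:
        Y = np.maximum(Y, 0.0)
    m = dict(meta or {})
    m.setdefault("seed", seed)
    m.setdefault("noise_sd", noise_sd)
    return EMGEnvelope(Y, fs, list(bank.channel_names), m,
                       [{"step": "synthesize_envelope", "noise_sd": noise_sd}])


def synthesize_raw_emg(
    envelope: EMGEnvelope,
    carrier_band: tuple[float, float] = (20.0, 400.0),
    pli_freq: float = 50.0,
    pli_amp: float = 0.0,
    spike_rate: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
    fs_out: float = 2000.0,
) -> RawEMG:
    """Turn an activation envelope into a raw-like EMG signal.

    The (upsampled, zero-floored) envelope amplitude-modulates a zero-mean
    band-limited Gaussian carrier; sinusoidal PLI at ``pli_freq`` and its
    first three harmonics (amplitude ``pli_amp/k`` for harmonic k), a
    constant baseline, and random impulsive spikes at ``spike_rate`` per
    second per channel are added on top.
    """
    if carrier_band[1] >= fs_out / 2.0:
        raise ValueError(
            f"carrier band {carrier_band} exceeds Nyquist at fs_out={fs_out}"
        )
    rng = np.random.default_rng(seed)
    env = np.maximum(envelope.data, 0.0)
    if fs_out != envelope.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / envelope.fs).limit_denominator(1000)
        env = resample_poly(env, frac.numerator, frac.denominator, axis=1)
        env = np.maximum(env, 0.0)
    n_ch, n = env.shape
    carrier = rng.standard_normal((n_ch, n))
    sos = butter(4, list(carrier_band), btype="bandpass", fs=fs_out, output="sos")
    carrier = sosfiltfilt(sos, carrier, axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)
    x = env * carrier
    t = np.arange(n) / fs_out
    if pli_amp:
        for k in range(1, 5):
            phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
            x += (pli_amp / k) * np.sin(2 * np.pi * k * pli_freq * t + phase)
    x += baseline
    if spike_rate > 0:
        amp_scale = max(x.std(), 1e-12)
        for c in range(n_ch):
            n_spikes = rng.poisson(spike_rate * n / fs_out)
            if n_spikes:
                pos = rng.integers(0, n, size=n_spikes)
                amp = rng.uniform(5, 10, size=n_spikes) * amp_scale
                x[c, pos] += amp * rng.choice([-1.0, 1.0], size=n_spikes)
    meta = dict(envelope.meta)
    meta["raw_seed"] = seed
    return RawEMG(x, fs_out, list(envelope.channel_names), meta)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class StyleEffect:
    """A planted additive weight shift on one (template, channel).

    ``factor='tempo'`` adds ``shift`` at fast styles; ``factor='force'``
    adds it at soft styles.  A positive shift on a negative weight makes it
    *less negative* at fast (or soft), the direction reported in real data.
    """

    template: int
    channel: int
    factor: str  # 'tempo' | 'force'
    shift: float


def _default_age_groups(subjects: Sequence[str]) -> dict:
    n = len(subjects)
    groups = {}
    n_young = max(1, round(0.4 * n))
    n_old = 1 if n >= 3 else 0
    for i, s in enumerate(subjects):
        if i < n_young:
            groups[s] = "under30"
        elif i >= n - n_old:
            groups[s] = "over50"
        else:
            groups[s] = "mid"
    return groups


def _default_expertise(subjects: Sequence[str]) -> dict:
    n = len(subjects)
    n_junior = max(1, round(0.4 * n))
    return {s: ("junior" if i < n_junior else "senior")
            for i, s in enumerate(subjects)}


@dataclass
class CohortConfig:
    """Design of a synthetic cohort.

    Defaults emulate the study conditions: 10 expert subjects in three age
    groups (4/5/1) and two expertise groups, five tasks (three scales
    repeated twice per style, two pieces played once) at the four
    tempo-force styles, 14 channels per side, 60 s trials at a 100 Hz
    envelope rate.
    """

    n_subjects: int = 10
    age_groups: Mapping[str, str] | None = None
    expertise: Mapping[str, str] | None = None
    tasks: Sequence[str] = field(default_factory=lambda: list(DEFAULT_TASKS))
    styles: Sequence[str] = field(default_factory=lambda: list(STYLES))
    sides: Sequence[str] = field(default_factory=lambda: ["L", "R"])
    reps_per_task: Mapping[str, int] | None = None
    n_channels: int = 14
    n_synergies_true: int = 5
    inhibitory_fraction: float = 0.2
    duration_s: float = 60.0
    fs: float = 100.0
    smoothness_ms: float = 100.0
    activation_shift: float = 0.3
    noise_sd: float = 0.02
    subject_jitter_sd: float = 0.1
    trial_jitter_sd: float = 0.05
    proportion_effect: float = 0.0
    proportion_effect_group: str = "over50"
    style_effects: Sequence[StyleEffect] = field(default_factory=list)
    floor_at_zero: bool = True
    seed: int = 0

    def __post_init__(self):
        if sorted(self.styles) != sorted(STYLES):
            raise ValueError(
                f"styles must be the four tempo-force combinations {STYLES}"
            )
        self.subjects = [f"s{i + 1:02d}" for i in range(self.n_subjects)]
        if self.age_groups is None:
            self.age_groups = _default_age_groups(self.subjects)
        if self.expertise is None:
            self.expertise = _default_expertise(self.subjects)
        for s in self.subjects:
            if s not in self.age_groups or s not in self.expertise:
                raise ValueError(f"subject {s} missing an age or expertise label")
        if self.reps_per_task is None:
            self.reps_per_task = {
                t: (2 if not t.startswith("piece") else 1) for t in self.tasks
            }


@dataclass
class Cohort:
    """Simulated trials plus the ground truth that generated them."""

    config: CohortConfig
    bank: GroundTruthBank
    trials: list  # EMGEnvelope (or RawEMG when emitting raw signals)
    trial_truth: list  # dict per trial: realized W, proportions, labels
    manifest: dict


def _validate_effects(config: CohortConfig, bank: GroundTruthBank) -> None:
    for eff in config.style_effects:
        if not (0 <= eff.template < bank.n_synergies):
            raise ValueError(f"style effect references unknown template {eff.template}")
        if not (0 <= eff.channel < bank.n_channels):
            raise ValueError(f"style effect references unknown channel {eff.channel}")
        if eff.factor not in ("tempo", "force"):
            raise ValueError(f"unknown contrast factor {eff.factor!r}")


def simulate_cohort(config: CohortConfig, emit_signals: bool = True) -> Cohort:
    """Generate one full labelled cohort.

    Per (subject, side, task, style) cell, ``reps_per_task[task]`` trials
    are generated.  The realized per-trial template matrix is

        ``W_trial = (W_group + style shifts) * subject jitter * trial jitter``

    where ``W_group`` scales the negative entries of the base templates by
    ``(1 + proportion_effect)`` for subjects in the designated group, and
    jitters are per-entry lognormal (sign preserving).  ``trial_truth``
    records every realized matrix and its inhibitory proportions;
    ``manifest`` summarizes the planted effects and seeds.

    With ``emit_signals=False`` only the ground truth is generated (fast
    path for statistical calibration studies).
    """
    seed = config.seed
    bank = make_synergy_bank(
        config.n_channels, config.n_synergies_true, config.inhibitory_fraction,
        seed=derive_seed(seed, "bank"),
    )
    _validate_effects(config, bank)
    n_samples = int(round(config.duration_s * config.fs))
    trials, truths = [], []
    for subject in config.subjects:
        age = config.age_groups[subject]
        exp = config.expertise[subject]
        W_group = bank.W_true.copy()
        if config.proportion_effect and (
            age == config.proportion_effect_group
            or exp == config.proportion_effect_group
        ):
            negm = W_group < 0
            W_group[negm] *= 1.0 + config.proportion_effect
        for side in config.sides:
            rng_subj = derive_rng(seed, "subject", subject, side)
            subj_jitter = np.exp(
                config.subject_jitter_sd
                * rng_subj.standard_normal(W_group.shape)
            )
            for task in config.tasks:
                for style in config.styles:
                    for rep in range(config.reps_per_task[task]):
                        key = (subject, side, task, style, rep)
                        W_style = W_group.copy()
                        for eff in config.style_effects:
                            hit = (
                                (eff.factor == "tempo" and style[0] == "F")
                                or (eff.factor == "force" and style[1] == "S")
                            )
                            if hit:
                                W_style[eff.channel, eff.template] += eff.shift
                        rng_t = derive_rng(seed, "trial", *key)
                        trial_jitter = np.exp(
                            config.trial_jitter_sd
                            * rng_t.standard_normal(W_style.shape)
                        )
                        W_trial = W_style * subj_jitter * trial_jitter
                        absW = np.abs(W_trial)
                        props = (
                            np.where(W_trial < 0, absW, 0.0).sum(axis=0)
                            / absW.sum(axis=0)
                        )
                        meta = {
                            "subject": subject, "side": side, "task": task,
                            "style": style, "rep": rep, "age_group": age,
                            "expertise": exp,
                        }
                        truths.append(
                            {"W_trial": W_trial, "proportions": props, **meta}
                        )
                        if emit_signals:
                            C = simulate_activations(
                                n_samples, config.n_synergies_true,
                                config.smoothness_ms, config.fs,
                                seed=derive_seed(seed, "act", *key),
                                shift=config.activation_shift,
                            )
                            env = synthesize_envelope(
                                GroundTruthBank(W_trial, bank.channel_names,
                                                bank.inhibitory_mask),
                                C, config.noise_sd,
                                seed=derive_seed(seed, "noise", *key),
                                floor_at_zero=config.floor_at_zero,
                                fs=config.fs, meta=meta,
                            )
                            trials.append(env)
    manifest = {
        "seed": seed,
        "n_subjects": config.n_subjects,
        "subjects": list(config.subjects),
        "age_groups": dict(config.age_groups),
        "expertise": dict(config.expertise),
        "tasks": list(config.tasks),
        "styles": list(config.styles),
        "sides": list(config.sides),
        "n_channels": config.n_channels,
        "n_synergies_true": config.n_synergies_true,
        "planted_effects": {
            "proportion_effect": config.proportion_effect,
            "proportion_effect_group": (
                config.proportion_effect_group if config.proportion_effect else None
            ),
            "style_effects": [
                {"template": e.template, "channel": e.channel,
                 "factor": e.factor, "shift": e.shift}
                for e in config.style_effects
            ],
        },
        "template_inhibitory_proportions": [
            float(p) for p in bank.inhibitory_proportions()
        ],
        "n_trials": len(truths),
    }
    return Cohort(config, bank, trials, truths, manifest)
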
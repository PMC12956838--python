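"""Synthetic pupillometry study generator.

Emulates a passive-viewing study: 40 participants x 50 grayscale stimuli
(25 positive, 25 negative), monocular pupil diameter at 60 fps for 360
frames per trial.  Each trial follows a constriction-then-recovery template
(smooth fall from baseline 100 to ``100 - C`` at ``t_min``, exponential
relaxation toward a plateau), with:

* valence encoded in constriction depth, time-to-minimum, recovery plateau
  and noise variance (negative stimuli constrict deeper and faster, recover
  less, and fluctuate more);
* a spatial-frequency effect on sustained constriction (higher SF lowers
  the post-minimum level);
* arousal scaling the overall response amplitude;
* per-participant baseline diameter and response heterogeneity;
* AR(1) Gaussian measurement noise; and
* injectable blink dropouts and single-frame spikes exercising the cleaning
  rules.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import zlib

import numpy as np

from .stimulus import assign_arousal_level, assign_sf_level
from .types import RawPupilTrace, StimulusMeta, ValidationError

__all__ = [
    "GeneratorConfig",
    "WaveformParams",
    "generate_stimulus_set",
    "generate_clean_trace",
    "sample_trial",
    "inject_artifacts",
    "generate_grating_image",
    "generate_dataset",
]

# Reference distribution of the SF score in the emulated stimulus set:
# per-level score ranges and level counts for 50 stimuli (7/11/10/11/11),
# plus the pooled mean/sd used to standardize scores.
_SF_RANGES = ((5.40, 6.95), (7.19, 11.06), (11.08, 13.30), (13.32, 17.68), (17.93, 47.82))
_SF_LEVEL_WEIGHTS = (7, 11, 10, 11, 11)
_SF_MEAN, _SF_SD = 14.27, 8.61
# arousal level proportions over (low, mid, high) for 50 stimuli: 7/25/18
_AROUSAL_WEIGHTS = {"low": 7, "mid": 25, "high": 18}
_AROUSAL_RATINGS = {"low": (1, 2), "mid": (3, 4, 5), "high": (6, 7)}

_AROUSAL_INDEX = {"low": 0, "mid": 1, "high": 2}


@dataclass
class GeneratorConfig:
    """Study-design and effect-size parameters of the generator.

    Pairs are (positive, negative).  ``valence_effect_size`` scales each
    pair's deviation from its midpoint, so 0 gives identical class
    distributions and 1 gives the documented defaults.
    """

    n_participants: int = 40
    n_positive: int = 25
    n_negative: int = 25
    frames_per_trial: int = 360
    constriction_depth_by_valence: tuple[float, float] = (20.0, 25.0)  # D_RATIO units
    drop_latency_by_valence: tuple[float, float] = (55.0, 45.0)  # frames
    recovery_plateau_by_valence: tuple[float, float] = (103.0, 99.0)  # D_RATIO units
    valence_effect_size: float = 1.0
    sf_constriction_gain: float = 2.5  # D_RATIO units per SD of the SF score
    arousal_amplitude_gain: float = 1.1  # multiplier per arousal level step
    noise_sd: float = 2.0  # stationary AR(1) sd, D_RATIO units
    ar_coefficient: float = 0.8
    negative_noise_inflation: float = 0.5  # extra noise fraction at effect size 1
    blink_rate: float = 0.5  # expected blinks per trial
    blink_duration_range: tuple[int, int] = (3, 36)  # frames, inclusive
    spike_rate: float = 0.5  # expected single-frame spikes per trial
    recovery_tau: float = 80.0  # frames
    participant_effect_sd: float = 0.3  # heterogeneity of the valence effect
    participant_amplitude_sd: float = 0.1  # heterogeneity of response amplitude
    # trial-to-trial response variability (attentional/state fluctuations):
    trial_effect_sd: float = 0.6  # per-trial multiplier on the valence effect
    latency_jitter_frames: float = 6.0  # additive jitter on time-to-minimum
    level_jitter: float = 2.0  # additive jitter on the recovery plateau
    depth_jitter: float = 2.0  # additive jitter on constriction depth
    noise_scale_log_sd: float = 0.25  # lognormal jitter on the noise sd
    baseline_mean_mm: float = 4.0
    baseline_sd_mm: float = 0.5
    seed: int = 1004

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_positive + self.n_negative) < 1:
            raise ValidationError("counts must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValidationError("ar_coefficient must be in [0, 1)")
        if self.valence_effect_size < 0:
            raise ValidationError("valence_effect_size must be >= 0")


@dataclass
class WaveformParams:
    """Parameters of the deterministic constriction-recovery template."""

    constriction_depth: float  # C, D_RATIO units
    time_to_minimum: int  # t_min, 1-based frame of the minimum
    recovery_tau: float  # frames
    plateau: float  # P_end, D_RATIO units
    baseline_level: float = 100.0

    def __post_init__(self) -> None:
        if self.constriction_depth < 0:
            raise ValidationError("constriction depth must be >= 0")
        if self.time_to_minimum < 1:
            raise ValidationError("time_to_minimum must be >= 1")
        if self.constriction_depth > 0 and self.time_to_minimum < 2:
            raise ValidationError(
                "a non-zero constriction needs time_to_minimum >= 2"
            )
        if self.recovery_tau <= 0:
            raise ValidationError("recovery_tau must be positive")
        if self.plateau < self.baseline_level - self.constriction_depth:
            raise ValidationError("plateau must be >= baseline - depth")


def _allocate(weights, n: int) -> list[int]:
    """Largest-remainder allocation of n items to weighted groups."""
    w = np.asarray(weights, dtype=float)
    quota = w / w.sum() * n
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_stimulus_set(config: GeneratorConfig) -> list[StimulusMeta]:
    """Draw stimulus metadata mirroring the reference stimulus-set design.

    Valence counts match the config; SF scores are drawn uniformly within
    the five reference level ranges with level counts allocated in the
    reference proportions (all five levels non-empty at default counts);
    arousal ratings follow the reference low/mid/high proportions; mean
    luminance is tightly normalized around 127.5.  Visual/arousal
    properties are assigned independently of valence.
    """
    n = config.n_positive + config.n_negative
    if n < 2:
        raise ValidationError("need at least 2 stimuli")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    level_counts = _allocate(_SF_LEVEL_WEIGHTS, n)
    sf_values = []
    for lvl, cnt in enumerate(level_counts, start=1):
        lo, hi = _SF_RANGES[lvl - 1]
        sf_values.extend(rng.uniform(lo, hi, size=cnt))
    sf_values = np.array(sf_values)
    rng.shuffle(sf_values)

    arousal_counts = _allocate(list(_AROUSAL_WEIGHTS.values()), n)
    ratings = []
    for level, cnt in zip(_AROUSAL_WEIGHTS, arousal_counts):
        ratings.extend(rng.choice(_AROUSAL_RATINGS[level], size=cnt))
    ratings = np.array(ratings)
    rng.shuffle(ratings)

    valences = ["positive"] * config.n_positive + ["negative"] * config.n_negative
    width = max(2, len(str(n)))
    stimuli = []
    for i in range(n):
        sf = float(sf_values[i])
        rating = int(ratings[i])
        stimuli.append(
            StimulusMeta(
                stimulus_id=f"s{i + 1:0{width}d}",
                valence=valences[i],
                arousal_rating=rating,
                arousal_level=assign_arousal_level(rating),
                sf_value=sf,
                sf_level=assign_sf_level(sf),
                mean_luminance=float(rng.normal(127.52, 0.07)),
            )
        )
    return stimuli


def generate_clean_trace(params: WaveformParams, frames: int) -> np.ndarray:
    """Noiseless constriction-recovery template, 1-based frames 1..frames.

    Frame 1 equals the baseline level (100); the minimum ``100 - C`` is
    attained at ``t_min`` via a smooth half-cosine fall; afterwards the
    trace relaxes exponentially toward the plateau with time constant tau.
    """
    if frames < params.time_to_minimum:
        raise ValidationError("frames must be >= time_to_minimum")
    b, c = params.baseline_level, params.constriction_depth
    t_min, tau, p_end = params.time_to_minimum, params.recovery_tau, params.plateau
    t = np.arange(1, frames + 1, dtype=float)
    d = np.empty(frames)
    fall = t <= t_min
    if t_min > 1:
        phase = (t[fall] - 1) / (t_min - 1)
        d[fall] = b - c * (1 - np.cos(np.pi * phase)) / 2.0
    else:
        d[fall] = b
    rise = ~fall
    d[rise] = p_end + (b - c - p_end) * np.exp(-(t[rise] - t_min) / tau)
    return d


def _valence_pair(pair, es: float, is_negative: bool, effect_mult: float = 1.0):
    mid = (pair[0] + pair[1]) / 2.0
    half = (pair[1] - pair[0]) / 2.0
    sign = 1.0 if is_negative else -1.0
    return mid + sign * es * half * effect_mult


def _participant_profile(participant_id: str, config: GeneratorConfig):
    """Deterministic per-participant baseline and heterogeneity multipliers."""
    key = zlib.crc32(participant_id.encode())
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, key]))
    baseline = max(2.0, rng.normal(config.baseline_mean_mm, config.baseline_sd_mm))
    effect_mult = max(0.0, rng.normal(1.0, config.participant_effect_sd))
    amp_mult = max(0.1, rng.normal(1.0, config.participant_amplitude_sd))
    return baseline, effect_mult, amp_mult


def trial_waveform_params(
    meta: StimulusMeta,
    config: GeneratorConfig,
    effect_mult: float = 1.0,
    jitter: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> WaveformParams:
    """Resolve the template parameters for one trial.

    ``effect_mult`` scales the valence deviation from the class midpoint
    (participant x trial state); ``jitter`` adds valence-independent
    (depth, latency, plateau) perturbations emulating trial-to-trial
    attentional fluctuations.
    """
    es = config.valence_effect_size
    neg = meta.valence == "negative"
    c = _valence_pair(config.constriction_depth_by_valence, es, neg, effect_mult)
    t_min = _valence_pair(config.drop_latency_by_valence, es, neg, effect_mult)
    p_end = _valence_pair(config.recovery_plateau_by_valence, es, neg, effect_mult)
    z_sf = (meta.sf_value - _SF_MEAN) / _SF_SD
    c = c + config.sf_constriction_gain * z_sf + jitter[0]
    t_min = t_min + jitter[1]
    p_end = p_end - config.sf_constriction_gain * z_sf + jitter[2]
    c = float(np.clip(c, 0.0, 95.0))
    t_min = int(np.clip(round(t_min), 2, config.frames_per_trial))
    p_end = float(max(p_end, 100.0 - c))
    return WaveformParams(
        constriction_depth=c,
        time_to_minimum=t_min,
        recovery_tau=config.recovery_tau,
        plateau=p_end,
    )


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t - 1]
    return e


def sample_trial(
    meta: StimulusMeta,
    participant_id: str,
    config: GeneratorConfig,
    seed: int,
) -> RawPupilTrace:
    """One noisy (artifact-free) trial in raw device units.

    Deterministic given ``seed``; participant baseline and heterogeneity are
    derived from the config seed and participant id, so the same participant
    behaves consistently across trials.
    """
    baseline, effect_mult, amp_mult = _participant_profile(participant_id, config)
    rng = np.random.default_rng(seed)
    trial_mult = max(0.0, rng.normal(1.0, config.trial_effect_sd))
    jitter = (
        rng.normal(0.0, config.depth_jitter),
        rng.normal(0.0, config.latency_jitter_frames),
        rng.normal(0.0, config.level_jitter),
    )
    params = trial_waveform_params(meta, config, effect_mult * trial_mult, jitter)
    d = generate_clean_trace(params, config.frames_per_trial)

    gain = config.arousal_amplitude_gain ** _AROUSAL_INDEX[meta.arousal_level]
    d = 100.0 + (d - 100.0) * gain * amp_mult

    noise_mult = float(rng.lognormal(0.0, config.noise_scale_log_sd))
    if meta.valence == "negative":
        noise_mult *= 1.0 + config.negative_noise_inflation * config.valence_effect_size
    d = d + _ar1_noise(
        rng, config.frames_per_trial, config.noise_sd * noise_mult,
        config.ar_coefficient,
    )
    return RawPupilTrace(
        participant_id=participant_id,
        stimulus_id=meta.stimulus_id,
        values=d / 100.0 * baseline,
        baseline=baseline,
    )


def inject_artifacts(
    trace: RawPupilTrace, config: GeneratorConfig, seed: int
) -> RawPupilTrace:
    """Add blink-like dropout runs and single-frame spikes to a trial.

    Blink counts are Poisson(``blink_rate``) with run lengths uniform over
    ``blink_duration_range``; dropout values fall well below the D_RATIO 40
    gate.  Spike counts are Poisson(``spike_rate``); each spike exceeds the
    10% frame-to-frame jump threshold for exactly one frame.  Deterministic
    given ``seed``; zero rates return the input unchanged.
    """
    if config.blink_rate == 0 and config.spike_rate == 0:
        return trace
    rng = np.random.default_rng(seed)
    values = trace.values.copy()
    n = values.size
    lo, hi = config.blink_duration_range
    for _ in range(rng.poisson(config.blink_rate)):
        dur = int(rng.integers(lo, hi + 1))
        if dur >= n - 2:
            dur = n - 3
        start = int(rng.integers(1, n - dur))  # interior placement
        values[start : start + dur] *= rng.uniform(0.10, 0.35)
    for _ in range(rng.poisson(config.spike_rate)):
        pos = int(rng.integers(1, n - 1))
        direction = 1.0 if rng.random() < 0.5 else -1.0
        values[pos] *= 1.0 + direction * rng.uniform(0.12, 0.25)
    return RawPupilTrace(
        participant_id=trace.participant_id,
        stimulus_id=trace.stimulus_id,
        values=values,
        baseline=trace.baseline,
    )


def generate_grating_image(
    cycles_per_image: float, size_px: int = 128, contrast: float = 1.0
) -> np.ndarray:
    """Sinusoidal grating on a 0-255 scale: mean 127.5, amplitude contrast*127.5."""
    if cycles_per_image < 0:
        raise ValidationError("cycles_per_image must be >= 0")
    if size_px < 8:
        raise ValidationError("size_px must be >= 8")
    x = np.arange(size_px)
    row = 127.5 + contrast * 127.5 * np.sin(2.0 * np.pi * cycles_per_image * x / size_px)
    return np.tile(row, (size_px, 1))


def generate_dataset(
    config: GeneratorConfig, with_artifacts: bool = True
) -> tuple[list[RawPupilTrace], list[StimulusMeta]]:
    """The full synthetic study: every participant x every stimulus.

    Trial seeds are derived from (config.seed, participant index, stimulus
    index), so the dataset is fully reproducible and any sub-design is a
    subset of the full one.
    """
    stimuli = generate_stimulus_set(config)
    width = max(2, len(str(config.n_participants)))
    trials = []
    for p_idx in range(config.n_participants):
        pid = f"p{p_idx + 1:0{width}d}"
        for s_idx, meta in enumerate(stimuli):
            ss = np.random.SeedSequence([config.seed, 3, p_idx, s_idx])
            trial_seed, artifact_seed = ss.generate_state(2).tolist()
            trial = sample_trial(meta, pid, config, seed=trial_seed)
            if with_artifacts:
                trial = inject_artifacts(trial, config, seed=artifact_seed)
            trials.append(trial)
    return trials, stimuli
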
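"""Synthetic 90 Hz gaze-stream and cohort generation.

Emulates the binocular-VR eye-tracking recordings the analysis consumes:
4-second free-viewing trials sampled at 90 Hz, with per-group focal
dwell levels, angular measurement error (accuracy 0.84°, precision
0.16°), sporadic sample drop-out, and occasional blink gaps.

The generative target process is a two-state semi-Markov alternation
between focal-object looks and background looks.  State durations are
shifted-exponential (minimum look 100 ms) with means chosen so that the
expected fraction of trial time in the focal state equals the requested
dwell fraction.  During focal states the gaze ray aims at the chosen
object's collider center; during background states it aims well away
from both colliders.  Accuracy error is a fixed per-trial angular offset
(uniform direction, Rayleigh magnitude); precision error is per-sample
isotropic Gaussian jitter.

A single cohort seed fans out to per-participant child seeds (keyed by
participant index) so cohorts are reproducible and extensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scene_model import SceneSpec

__all__ = [
    "GroupProfile",
    "GazeSample",
    "MIN_LOOK_MS",
    "generate_trial_stream",
    "generate_trial_arrays",
    "generate_cohort",
    "draw_participant_dwell",
    "draw_participant_metadata",
    "iter_participant_trials",
    "participant_rng",
    "gaze_log_to_samples",
]

SAMPLING_HZ = 90.0
MIN_LOOK_MS = 100.0       # minimum semi-Markov state duration
BLINK_RANGE_MS = (100.0, 300.0)


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one cultural group.

    ``target_focal_dwell_mean/sd`` are milliseconds of focal dwell per
    4-s trial (between-participant distribution); ``closer_further_delta``
    is the mean extra dwell on the closer object in varied-distance
    scenes; ``data_loss_rate`` is the per-sample drop-out probability,
    on top of which blink gaps contribute about
    ``blink_rate_per_trial * 200 ms / trial_duration`` additional loss.
    """

    group_name: str
    n_participants: int
    target_focal_dwell_mean: float
    target_focal_dwell_sd: float
    closer_further_delta: float = 0.0
    data_loss_rate: float = 0.004
    noise_accuracy_deg: float = 0.84
    noise_precision_deg: float = 0.16
    blink_rate_per_trial: float = 0.04
    female_fraction: float = 0.5
    age_mean: float = 22.0
    age_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.data_loss_rate <= 1:
            raise ValueError("data_loss_rate must be in [0, 1]")
        if self.target_focal_dwell_sd < 0:
            raise ValueError("target_focal_dwell_sd must be nonnegative")
        if self.target_focal_dwell_mean < 0:
            raise ValueError("target dwell mean must be nonnegative")


@dataclass(frozen=True)
class GazeSample:
    """One 90 Hz eye-tracker record: a timestamped gaze ray plus validity."""

    participant_id: str
    trial_id: str
    timestamp_ms: float
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    valid: bool


def _tangent_basis(target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the plane perpendicular to a unit direction."""
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(target, z)
    n = np.linalg.norm(e1)
    if n < 1e-12:  # target parallel to z: use y axis
        e1 = np.array([0.0, 1.0, 0.0])
    else:
        e1 = e1 / n
    e2 = np.cross(target, e1)
    return e1, e2


def _perturb_directions(targets: np.ndarray, offsets_deg: np.ndarray) -> np.ndarray:
    """Rotate unit directions by small angular offsets in the tangent plane."""
    rad = np.deg2rad(offsets_deg)
    out = np.empty_like(targets)
    for i, t in enumerate(targets):
        e1, e2 = _tangent_basis(t)
        out[i] = t + rad[i, 0] * e1 + rad[i, 1] * e2
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _state_schedule(
    rng: np.random.Generator, dwell_fraction: float, duration_ms: float
) -> list[tuple[float, float, bool]]:
    """Semi-Markov (start, end, is_focal) episodes covering the trial."""
    f = float(dwell_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("dwell_fraction must be in [0, 1]")
    if f == 0.0:
        return [(0.0, duration_ms, False)]
    if f == 1.0:
        return [(0.0, duration_ms, True)]
    # cycle length chosen so both state means respect the minimum look
    cycle = max(1000.0, MIN_LOOK_MS / f, MIN_LOOK_MS / (1.0 - f))
    means = {True: f * cycle, False: (1.0 - f) * cycle}
    episodes = []
    t = 0.0
    focal = bool(rng.random() < f)  # stationary start avoids onset bias
    while t < duration_ms:
        m = means[focal]
        dur = MIN_LOOK_MS + rng.exponential(m - MIN_LOOK_MS) if m > MIN_LOOK_MS else m
        episodes.append((t, min(t + dur, duration_ms), focal))
        t += dur
        focal = not focal
    return episodes


def generate_trial_arrays(
    profile: GroupProfile,
    scene: SceneSpec,
    dwell_fraction: float,
    rng: np.random.Generator,
    closer_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast array-based trial generation.

    Returns ``(timestamps_ms, directions, valid)`` for one trial.
    ``closer_fraction`` is the probability that a focal look targets the
    closer-classed object (0.5 for equal-distance scenes).
    """
    if len(scene.objects) != 2:
        raise ValueError("scene must carry two colliders")
    duration = scene.trial_duration_ms
    n = int(round(duration * SAMPLING_HZ / 1000.0))
    ts = np.arange(n) * (1000.0 / SAMPLING_HZ)

    cache = scene.__dict__.get("_aim_cache")
    if cache is None:
        centers = np.array([o.collider.centroid for o in scene.objects])
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        # background aim: upward, away from the focal objects near the horizon
        bg_dir = np.array([0.0, np.sin(np.deg2rad(30.0)), np.cos(np.deg2rad(30.0))])
        # three possible aim points: the two object centers and background
        aims = np.vstack([centers, bg_dir])
        bases = np.array([np.vstack(_tangent_basis(a)) for a in aims])  # (3, 2, 3)
        cache = (aims, bases)
        scene.__dict__["_aim_cache"] = cache
    aims, bases = cache

    ci = scene.closer_index
    episodes = _state_schedule(rng, dwell_fraction, duration)
    starts = np.array([e[0] for e in episodes])
    idx = np.searchsorted(starts, ts, side="right") - 1
    aim_idx = np.empty(len(episodes), dtype=np.intp)
    for k, (_, _, focal) in enumerate(episodes):
        if focal:
            if ci is None:
                aim_idx[k] = int(rng.random() < 0.5)
            else:
                aim_idx[k] = ci if rng.random() < closer_fraction else 1 - ci
        else:
            aim_idx[k] = 2
    per_sample = aim_idx[idx]
    targets = aims[per_sample]

    # accuracy: fixed per-trial offset; precision: per-sample jitter
    mag = rng.rayleigh(profile.noise_accuracy_deg)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    offset = mag * np.array([np.cos(theta), np.sin(theta)])
    rad = np.deg2rad(offset[None, :] + rng.normal(0.0, profile.noise_precision_deg, size=(n, 2)))
    e1 = bases[per_sample, 0]
    e2 = bases[per_sample, 1]
    directions = targets + rad[:, 0:1] * e1 + rad[:, 1:2] * e2
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    valid = rng.random(n) >= profile.data_loss_rate
    if rng.random() < profile.blink_rate_per_trial:
        b_dur = rng.uniform(*BLINK_RANGE_MS)
        b_start = rng.uniform(0.0, duration - b_dur)
        valid &= ~((ts >= b_start) & (ts < b_start + b_dur))
    return ts, directions, valid


def generate_trial_stream(
    profile: GroupProfile,
    scene: SceneSpec,
    participant_dwell_fraction: float,
    seed: int,
    participant_id: str = "p0",
    closer_fraction: float = 0.5,
) -> list[GazeSample]:
    """Generate one trial's gaze samples (object API over the array core)."""
    rng = np.random.default_rng(seed)
    ts, dirs, valid = generate_trial_arrays(
        profile, scene, participant_dwell_fraction, rng, closer_fraction
    )
    return [
        GazeSample(
            participant_id=participant_id,
            trial_id=scene.scene_id,
            timestamp_ms=float(t),
            origin=(0.0, 0.0, 0.0),
            direction=tuple(d),
            valid=bool(v),
        )
        for t, d, v in zip(ts, dirs, valid)
    ]


def draw_participant_dwell(
    profile: GroupProfile, rng: np.random.Generator, trial_duration_ms: float = 4000.0
) -> float:
    """Participant-level focal dwell drawn from a truncated normal.

    Truncation bounds [0, trial duration] because dwell cannot exceed
    the trial.
    """
    m, s = profile.target_focal_dwell_mean, profile.target_focal_dwell_sd
    if s == 0:
        return float(np.clip(m, 0.0, trial_duration_ms))
    a, b = (0.0 - m) / s, (trial_duration_ms - m) / s
    return float(
        stats.truncnorm.rvs(a, b, loc=m, scale=s, random_state=rng)
    )


def _closer_fraction(dwell_ms: float, delta_ms: float) -> float:
    """Probability a focal look targets the closer object.

    Chosen so expected closer-minus-further dwell equals ``delta_ms``
    given total focal dwell ``dwell_ms``; clipped to [0, 1].
    """
    if dwell_ms <= 0:
        return 0.5
    return float(np.clip(0.5 + delta_ms / (2.0 * dwell_ms), 0.0, 1.0))


def participant_rng(seed: int, pidx: int) -> np.random.Generator:
    """Child generator for participant ``pidx`` under the cohort seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(pidx,))
    )


def draw_participant_metadata(
    profile: GroupProfile,
    pid: str,
    rng: np.random.Generator,
    attrition: dict | None = None,
    trial_duration_ms: float = 4000.0,
) -> dict:
    """Participant metadata row, including the latent dwell level."""
    attrition = attrition or {}
    dwell = draw_participant_dwell(profile, rng, trial_duration_ms)
    return {
        "participant_id": pid,
        "group": profile.group_name,
        "gender": "F" if rng.random() < profile.female_fraction else "M",
        "age": float(np.clip(rng.normal(profile.age_mean, profile.age_sd), 18, 60)),
        "municipality_size": int(rng.integers(1, 6)),
        "lived_abroad": bool(rng.random() < 0.15),
        "n_siblings": int(rng.poisson(1.5)),
        "ses": int(rng.integers(1, 6)),
        "study_area": int(rng.integers(1, 7)),
        "adhd_history": bool(rng.random() < attrition.get("adhd", 0.0)),
        "validation_ok": not rng.random() < attrition.get("validation_fail", 0.0),
        "technical_failure": bool(
            rng.random() < attrition.get("technical_failure", 0.0)
        ),
        "target_dwell_ms": dwell,
    }


def iter_participant_trials(
    profile: GroupProfile,
    scenes: list[SceneSpec],
    rng: np.random.Generator,
    target_dwell_ms: float,
):
    """Yield ``(scene, timestamps, directions, valid)`` per trial.

    The per-trial draws continue the participant's RNG stream, so the
    full-log and streaming processing paths see identical data.
    """
    cf = _closer_fraction(target_dwell_ms, profile.closer_further_delta)
    for scene in scenes:
        frac = min(target_dwell_ms / scene.trial_duration_ms, 1.0)
        ts, dirs, valid = generate_trial_arrays(
            profile,
            scene,
            frac,
            rng,
            closer_fraction=cf if scene.closer_index is not None else 0.5,
        )
        yield scene, ts, dirs, valid


def generate_cohort(
    profiles: list[GroupProfile],
    scenes: list[SceneSpec],
    seed: int,
    attrition: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: participant metadata plus gaze log.

    ``attrition`` optionally plants exclusion-stage flags, e.g.
    ``{"technical_failure": 0.03, "validation_fail": 0.07, "adhd": 0.05}``
    (per-participant probabilities).  Defaults to a clean cohort.

    Returns ``(participants, gaze_log)`` data frames; the gaze log has
    columns participant_id, trial_id, t_ms, ox, oy, oz, dx, dy, dz,
    valid.  Reproducible given ``seed``.
    """
    if not profiles:
        raise ValueError("at least one group profile is required")
    meta_rows = []
    log_parts = []
    pidx = 0
    for profile in profiles:
        for _ in range(profile.n_participants):
            rng = participant_rng(seed, pidx)
            pid = f"{profile.group_name}_{pidx:04d}"
            meta = draw_participant_metadata(profile, pid, rng, attrition)
            meta_rows.append(meta)
            for scene, ts, dirs, valid in iter_participant_trials(
                profile, scenes, rng, meta["target_dwell_ms"]
            ):
                log_parts.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "trial_id": scene.scene_id,
                            "t_ms": ts,
                            "ox": 0.0,
                            "oy": 0.0,
                            "oz": 0.0,
                            "dx": dirs[:, 0],
                            "dy": dirs[:, 1],
                            "dz": dirs[:, 2],
                            "valid": valid,
                        }
                    )
                )
            pidx += 1
    participants = pd.DataFrame(meta_rows)
    gaze_log = pd.concat(log_parts, ignore_index=True)
    return participants, gaze_log


def gaze_log_to_samples(gaze_log: pd.DataFrame) -> list[GazeSample]:
    """Convert gaze-log rows to :class:`GazeSample` objects."""
    return [
        GazeSample(
            participant_id=str(r.participant_id),
            trial_id=str(r.trial_id),
            timestamp_ms=float(r.t_ms),
            origin=(float(r.ox), float(r.oy), float(r.oz)),
            direction=(float(r.dx), float(r.dy), float(r.dz)),
            valid=bool(r.valid),
        )
        for r in gaze_log.itertuples()
    ]
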
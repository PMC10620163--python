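"""Visit detection and dwell-time computation from labelled gaze samples.

The tracker samples at a nominal 90 Hz, so each sample carries a nominal
duration of 1000/90 ≈ 11.11 ms.  A maximal run of samples on the same
object is a candidate gaze episode.  Two rules turn episodes into visits:

* **merge rule** — an episode on object X, followed by a very short hit
  (< 32 ms, strict) on a *different* object, followed by a return to X,
  is merged into a single visit; the interruption's own duration is not
  credited to the visit.  Merging is applied iteratively left-to-right so
  chains of short interruptions collapse.  Missing-data gaps never
  trigger the rule: any run of invalid samples terminates an episode.
* **minimum-duration rule** — applied after merging, an episode survives
  as a visit only if its duration exceeds 50 ms (strict), the threshold
  for cognitive registration of an object.

Dwell time per object category is the sum of the durations of its
surviving visits.  Data loss per trial is the fraction of expected
samples that are invalid or absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene_model import HitLabel, SceneRole, SceneSpec, classify_rays

__all__ = [
    "Visit",
    "TrialMetrics",
    "ParticipantMetrics",
    "IncompleteParticipantError",
    "SAMPLE_INTERVAL_MS",
    "VISIT_THRESHOLD_MS",
    "MERGE_THRESHOLD_MS",
    "label_stream",
    "detect_visits",
    "visits_from_labels",
    "compute_trial_metrics",
    "aggregate_participant",
    "aggregate_participants_frame",
]

SAMPLE_INTERVAL_MS = 1000.0 / 90.0   # nominal 90 Hz inter-sample interval
VISIT_THRESHOLD_MS = 50.0            # survival requires duration > this
MERGE_THRESHOLD_MS = 32.0            # interruption requires duration < this


@dataclass(frozen=True)
class Visit:
    """A contiguous (possibly merged) gaze episode on one category."""

    label: HitLabel
    start_ms: float
    end_ms: float
    duration_ms: float   # on-object time only; merged interruptions excluded
    merged: bool = False


@dataclass(frozen=True)
class TrialMetrics:
    participant_id: str
    trial_id: str
    dwell_fo1_ms: float
    dwell_fo2_ms: float
    dwell_background_ms: float
    data_loss: float


@dataclass(frozen=True)
class ParticipantMetrics:
    participant_id: str
    group: str
    mean_focal_dwell_ms: float
    mean_closer_dwell_ms: float
    mean_further_dwell_ms: float
    mean_data_loss: float


class IncompleteParticipantError(ValueError):
    """A participant is missing required test trials."""


def label_stream(samples, scene: SceneSpec) -> list[tuple]:
    """Classify every sample of a trial stream against the scene.

    ``samples`` must be sorted by timestamp; each sample contributes the
    nominal 90 Hz inter-sample interval to whichever category it hits.
    """
    samples = list(samples)
    if not samples:
        return []
    ts = np.array([s.timestamp_ms for s in samples], dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("gaze samples must be sorted by strictly increasing timestamp")
    dirs = np.array([s.direction for s in samples], dtype=float)
    valid = np.array([s.valid for s in samples], dtype=bool)
    labels = classify_rays(dirs, valid, scene)
    return [(s, HitLabel(int(lab))) for s, lab in zip(samples, labels)]


def _run_length_encode(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal same-label runs as (label, start_index, count)."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    counts = np.diff(np.concatenate((starts, [len(labels)])))
    return [(int(labels[s]), int(s), int(c)) for s, c in zip(starts, counts)]


def visits_from_labels(
    labels: np.ndarray,
    dt_ms: float = SAMPLE_INTERVAL_MS,
    t0_ms: float = 0.0,
    visit_threshold_ms: float = VISIT_THRESHOLD_MS,
    merge_threshold_ms: float = MERGE_THRESHOLD_MS,
) -> list[Visit]:
    """Core visit detector over an integer label sequence.

    Merge pass first (short foreign hit between two episodes on the same
    object, missing gaps never merge), then the strict >50 ms survival
    threshold.  Episode durations are sample counts times ``dt_ms``.
    """
    labels = np.asarray(labels)
    runs = _run_length_encode(labels)
    missing = int(HitLabel.MISSING)

    # merge pass: left-to-right, iteratively collapsing short interruptions
    merged_runs: list[tuple[int, int, int, int, bool]] = []  # label, start, count, end_idx, merged
    i = 0
    while i < len(runs):
        lab, start, count = runs[i]
        end_idx = start + count
        was_merged = False
        if lab != missing:
            while (
                i + 2 < len(runs)
                and runs[i + 1][0] != missing
                and runs[i + 1][2] * dt_ms < merge_threshold_ms
                and runs[i + 2][0] == lab
            ):
                count += runs[i + 2][2]
                end_idx = runs[i + 2][1] + runs[i + 2][2]
                was_merged = True
                i += 2
        merged_runs.append((lab, start, count, end_idx, was_merged))
        i += 1

    visits = []
    for lab, start, count, end_idx, was_merged in merged_runs:
        if lab == missing:
            continue
        duration = count * dt_ms
        if duration > visit_threshold_ms:
            visits.append(
                Visit(
                    label=HitLabel(lab),
                    start_ms=t0_ms + start * dt_ms,
                    end_ms=t0_ms + end_idx * dt_ms,
                    duration_ms=duration,
                    merged=was_merged,
                )
            )
    return visits


def detect_visits(labeled, dt_ms: float = SAMPLE_INTERVAL_MS) -> list[Visit]:
    """Visit detection over ``label_stream`` output."""
    if not labeled:
        return []
    labels = np.array([int(lab) for _, lab in labeled], dtype=np.int8)
    t0 = float(labeled[0][0].timestamp_ms)
    return visits_from_labels(labels, dt_ms=dt_ms, t0_ms=t0)


def compute_trial_metrics(
    visits: list[Visit],
    samples,
    scene: SceneSpec,
    participant_id: str = "",
    trial_id: str = "",
    sampling_hz: float = 90.0,
) -> TrialMetrics:
    """Per-trial dwell times (sum of visit durations) and data loss."""
    dwell = {HitLabel.FO1: 0.0, HitLabel.FO2: 0.0, HitLabel.BACKGROUND: 0.0}
    for v in visits:
        dwell[v.label] += v.duration_ms
    expected = int(round(scene.trial_duration_ms * sampling_hz / 1000.0))
    n_valid = sum(1 for s in samples if s.valid)
    return TrialMetrics(
        participant_id=participant_id,
        trial_id=trial_id,
        dwell_fo1_ms=dwell[HitLabel.FO1],
        dwell_fo2_ms=dwell[HitLabel.FO2],
        dwell_background_ms=dwell[HitLabel.BACKGROUND],
        data_loss=(expected - n_valid) / expected,
    )


def aggregate_participant(
    trial_metrics: list[TrialMetrics] | pd.DataFrame,
    scenes: list[SceneSpec],
    group: str = "",
) -> ParticipantMetrics:
    """Aggregate one participant's trial metrics to the analysis units.

    Mean focal dwell (fo1 + fo2) over the 28 TEST trials; mean dwell on
    the closer- and further-placed object over the 12 VARIED trials;
    mean data loss over the TEST trials.  TRAINING trials are excluded.
    A participant missing any TEST trial raises
    :class:`IncompleteParticipantError` rather than silently averaging
    over fewer trials.
    """
    if isinstance(trial_metrics, pd.DataFrame):
        df = trial_metrics
    else:
        df = pd.DataFrame([t.__dict__ for t in trial_metrics])
    if df.empty:
        raise IncompleteParticipantError("no trial metrics supplied")
    pid = str(df["participant_id"].iloc[0])

    by_id = {s.scene_id: s for s in scenes}
    test_ids = [s.scene_id for s in scenes if s.role is SceneRole.TEST]
    varied_ids = [
        s.scene_id
        for s in scenes
        if s.role is SceneRole.TEST and s.closer_index is not None
    ]
    df = df.set_index("trial_id")
    missing = [t for t in test_ids if t not in df.index]
    if missing:
        raise IncompleteParticipantError(
            f"participant {pid} is missing test trials: {missing}"
        )
    test = df.loc[test_ids]
    focal = test["dwell_fo1_ms"] + test["dwell_fo2_ms"]

    closer_vals, further_vals = [], []
    for tid in varied_ids:
        row = df.loc[tid]
        ci = by_id[tid].closer_index
        closer_vals.append(row["dwell_fo1_ms"] if ci == 0 else row["dwell_fo2_ms"])
        further_vals.append(row["dwell_fo2_ms"] if ci == 0 else row["dwell_fo1_ms"])

    return ParticipantMetrics(
        participant_id=pid,
        group=group,
        mean_focal_dwell_ms=float(focal.mean()),
        mean_closer_dwell_ms=float(np.mean(closer_vals)) if closer_vals else np.nan,
        mean_further_dwell_ms=float(np.mean(further_vals)) if further_vals else np.nan,
        mean_data_loss=float(test["data_loss"].mean()),
    )


def aggregate_participants_frame(
    trial_metrics: pd.DataFrame,
    scenes: list[SceneSpec],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Participant-level metrics table from a trial-metrics table."""
    rows = []
    for pid, sub in trial_metrics.groupby("participant_id", sort=False):
        pm = aggregate_participant(
            sub, scenes, group=(groups or {}).get(str(pid), "")
        )
        rows.append(pm.__dict__)
    return pd.DataFrame(rows)
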
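"""Synthetic physiological signals, feature tables and labels.

The generators reproduce the statistical structure the transductive
method is designed for, so the whole pipeline can be exercised without
any recorded data:

* raw BVP pulse trains whose beat amplitude falls and heart rate rises
  with a latent stress level (peripheral vasoconstriction under stress);
* raw GSR traces made of a slow tonic drift plus Poisson-arriving skin
  conductance responses whose rate and amplitude grow with stress;
* Stroop-style label tracks: congruent segments carry raw labels 1-4 by
  difficulty level, incongruent segments 5-8, normalised to [0, 1] by
  (raw - 1) / 7;
* multi-subject feature tables with a shared stress response plus
  per-subject offsets and response deviations scaled by a heterogeneity
  parameter (strong between-subject dispersion, irregular within-subject
  structure), with optional geometric thinning of high labels to mimic
  label imbalance;
* an outlier scenario: a coherent low-stress cluster contaminated by
  feature-adjacent examples carrying mislabeled high labels.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import SignalRecord

__all__ = [
    "SubjectProfile",
    "StroopSegment",
    "StroopLabelTrack",
    "gen_stroop_labels",
    "gen_bvp_signal",
    "gen_gsr_signal",
    "gen_multisubject_features",
    "gen_outlier_scenario",
]

#: The eight normalised Stroop labels (raw 1..8 mapped by (raw-1)/7).
STROOP_LEVELS = np.arange(8) / 7.0


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str
    feature_offset: np.ndarray
    feature_scale: np.ndarray
    latent_map: np.ndarray  # per-level feature centroids (8 x n_features)
    noise_sd: float


@dataclass(frozen=True)
class StroopSegment:
    difficulty: int
    congruency: str  # "congruent" | "incongruent"
    start: float
    end: float

    @property
    def raw_label(self) -> int:
        return self.difficulty + (4 if self.congruency == "incongruent" else 0)

    @property
    def label(self) -> float:
        return (self.raw_label - 1) / 7.0


@dataclass
class StroopLabelTrack:
    """Piecewise-constant normalised label track over Stroop segments."""

    segments: list[StroopSegment]

    @property
    def duration(self) -> float:
        return self.segments[-1].end if self.segments else 0.0

    def value_at(self, t: float) -> float:
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg.label
        # past the last boundary: hold the final segment's label
        return self.segments[-1].label if self.segments else 0.0


def gen_stroop_labels(
    n_segments_per_level: int = 1,
    seed: int = 0,
    segment_duration: float = 20.0,
    start_time: float = 0.0,
) -> StroopLabelTrack:
    """Alternating congruent/incongruent segments over four difficulty levels.

    Raw labels follow the difficulty-graded scheme (congruent 1-4,
    incongruent 5-8); segment durations jitter by +-20% around
    ``segment_duration``.
    """
    if n_segments_per_level < 1:
        raise ValueError("n_segments_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    segments: list[StroopSegment] = []
    t = start_time
    for difficulty in range(1, 5):
        for _ in range(n_segments_per_level):
            for congruency in ("congruent", "incongruent"):
                dur = segment_duration * rng.uniform(0.8, 1.2)
                segments.append(StroopSegment(difficulty, congruency, t, t + dur))
                t += dur
    return StroopLabelTrack(segments)


def gen_bvp_signal(
    stress: float,
    duration: float = 10.0,
    fs: float = 128.0,
    seed: int = 0,
    start_time: float = 0.0,
    base_ibi: float = 0.9,
    ibi_jitter_sd: float = 0.01,
    noise_sd: float = 0.02,
    pulse_width_frac: float = 0.25,
    return_beats: bool = False,
):
    """Gaussian-bump pulse train with stress-dependent rate and amplitude.

    The inter-beat interval shrinks linearly with stress
    (``IBI = base_ibi - 0.25 * stress`` plus per-beat jitter) and the
    pulse amplitude falls as ``1 - 0.4 * stress``, emulating peripheral
    vasoconstriction.  The bump width scales with the IBI
    (``pulse_width_frac`` of it) so adjacent pulses overlap into a
    continuous oscillation whose troughs — the diastolic points — are
    well defined at every heart rate, as in a real photoplethysmogram.
    With ``return_beats`` the beat times are also returned as ground
    truth.
    """
    rng = np.random.default_rng(seed)
    ibi = base_ibi - 0.25 * float(stress)
    if duration < 2 * ibi:
        raise ValueError("duration too short for two pulses")
    beats = []
    t = 0.3 * ibi
    while t < duration:
        beats.append(t)
        t += max(0.3, ibi + rng.normal(0.0, ibi_jitter_sd))
    beats = np.array(beats)
    amp = 1.0 - 0.4 * float(stress)
    width = pulse_width_frac * ibi
    t_axis = np.arange(int(round(duration * fs))) / fs
    x = (amp * np.exp(-((t_axis[None, :] - beats[:, None]) ** 2) / (2 * width**2))).sum(axis=0)
    x += rng.normal(0.0, noise_sd, len(t_axis))
    rec = SignalRecord(channel="BVP", sampling_rate=fs, start_time=start_time, samples=x)
    return (rec, beats) if return_beats else rec


def _scr_kernel(t: np.ndarray, rise: float = 0.7, decay: float = 3.0) -> np.ndarray:
    """Fast-rise / slow-decay SCR shape, normalised to unit peak."""
    h = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return h / peak


def gen_gsr_signal(
    stress: float,
    duration: float = 30.0,
    fs: float = 4.0,
    seed: int = 0,
    start_time: float = 0.0,
    tonic_level: float = 2.0,
    drift_sd: float = 0.005,
    noise_sd: float = 0.005,
    event_times=None,
    return_events: bool = False,
):
    """Tonic random-walk baseline plus stress-driven SCR events.

    SCRs arrive as a Poisson process with rate ``0.05 + 0.25 * stress``
    per second and amplitude ``(0.1 + 0.4 * stress)`` microsiemens (+-20%
    per event); each event is a fast-rise / slow-decay bump.  Explicit
    ``event_times`` override the Poisson draw (useful for ground-truth
    peak-count checks).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration shorter than one sample period")
    t_axis = np.arange(n) / fs
    tonic = tonic_level + 0.5 * float(stress) + np.cumsum(rng.normal(0.0, drift_sd, n))
    if event_times is None:
        rate = 0.05 + 0.25 * float(stress)
        n_events = rng.poisson(rate * duration)
        event_times = np.sort(rng.uniform(0.0, duration, n_events))
    else:
        event_times = np.asarray(event_times, dtype=float)
    x = tonic.copy()
    base_amp = 0.1 + 0.4 * float(stress)
    for t0 in event_times:
        x += base_amp * rng.uniform(0.8, 1.2) * _scr_kernel(t_axis - t0)
    x += rng.normal(0.0, noise_sd, n)
    rec = SignalRecord(channel="GSR", sampling_rate=fs, start_time=start_time, samples=x)
    return (rec, np.asarray(event_times)) if return_events else rec


def _label_weights(imbalance: float) -> np.ndarray:
    if not 0.0 <= imbalance < 1.0:
        raise ValueError("imbalance must lie in [0, 1)")
    w = (1.0 - imbalance) ** np.arange(len(STROOP_LEVELS))
    return w / w.sum()


def _balanced_levels(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-level counts proportional to `weights` summing to n, shuffled."""
    counts = np.floor(weights * n).astype(int)
    while counts.sum() < n:
        counts[np.argmax(weights * n - counts)] += 1
    levels = np.repeat(np.arange(len(weights)), counts)
    rng.shuffle(levels)
    return levels


def gen_multisubject_features(
    n_subjects: int = 5,
    n_per_subject: int = 60,
    heterogeneity: float = 1.0,
    imbalance: float = 0.0,
    seed: int = 0,
    n_features: int = 6,
    noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, list[SubjectProfile]]:
    """Multi-subject labeled feature table with controllable dispersion.

    All subjects share one smooth label -> feature-centroid constellation
    (linear + quadratic in the label, over the eight Stroop levels).
    ``heterogeneity`` scales three departures from it per subject: a
    feature-space offset, a subject-specific *permutation* of the
    label-to-centroid assignment (a growing fraction of levels is
    reassigned as heterogeneity rises), and per-level centroid jitter.
    At 0 the population is one homogeneous map; at 2 every subject
    arranges its label clusters idiosyncratically, so an example that is
    feature-near across subjects often carries a conflicting label —
    the dispersed, individually-different regime the transductive model
    targets.  Per subject the labels are balanced across levels (the
    Stroop protocol presents equally many words per difficulty) and then
    thinned geometrically at the high end by ``imbalance``.
    """
    if min(n_subjects, n_per_subject, n_features) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    lin0 = rng.normal(0.0, 1.0, n_features)
    quad0 = rng.normal(0.0, 1.0, n_features)
    constellation = np.array([lin0 * y + quad0 * y**2 for y in STROOP_LEVELS])
    weights = _label_weights(imbalance)
    perm_fraction = min(1.0, 0.5 * heterogeneity)

    rows = []
    profiles: list[SubjectProfile] = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        offset = 0.2 * heterogeneity * rng.normal(0.0, 1.0, n_features)
        perm = np.arange(len(STROOP_LEVELS))
        k = int(round(len(STROOP_LEVELS) * perm_fraction))
        if k >= 2:
            chosen = rng.choice(len(STROOP_LEVELS), size=k, replace=False)
            perm[chosen] = rng.permutation(perm[chosen])
        jitter = 0.3 * heterogeneity * rng.normal(0.0, 1.0, (len(STROOP_LEVELS), n_features))
        centroids = constellation[perm] + offset + jitter
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                feature_offset=offset,
                feature_scale=np.ones(n_features),
                latent_map=centroids,
                noise_sd=noise_sd,
            )
        )
        for li in _balanced_levels(weights, n_per_subject, rng):
            x = centroids[li] + rng.normal(0.0, noise_sd, n_features)
            rows.append(
                {"subject_id": sid, "y": float(STROOP_LEVELS[li]), **{f"f{k}": x[k] for k in range(n_features)}}
            )
    return pd.DataFrame(rows), profiles


def gen_outlier_scenario(
    n_clean: int = 40,
    n_outliers: int = 5,
    seed: int = 0,
    n_test: int = 10,
    n_features: int = 4,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """A coherent low-stress cluster contaminated by mislabeled examples.

    Clean examples have labels near 0.15 and features generated from a
    smooth map of the label; outliers draw their *features* from the same
    clean distribution but carry mislabeled labels near 0.85, making them
    feature-adjacent yet label-aberrant.  Returns the training table, a
    boolean outlier-flag vector aligned with it, and a clean test table.
    """
    if n_outliers < 1:
        raise ValueError("n_outliers must be >= 1")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 1.0, n_features)
    slope = rng.normal(0.0, 1.0, n_features)

    def make(n: int, mislabel: bool):
        recs = []
        for _ in range(n):
            y_feat = rng.uniform(0.05, 0.25)
            x = mu + slope * y_feat + rng.normal(0.0, noise_sd, n_features)
            y = rng.uniform(0.75, 0.95) if mislabel else y_feat
            recs.append({"subject_id": "S01", "y": float(y), **{f"f{k}": x[k] for k in range(n_features)}})
        return recs

    train = make(n_clean, mislabel=False) + make(n_outliers, mislabel=True)
    flags = np.array([False] * n_clean + [True] * n_outliers)
    test = pd.DataFrame(make(n_test, mislabel=False))
    return pd.DataFrame(train), flags, test
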
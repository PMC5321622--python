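"""Synthetic lateral-view swallow kinematics with known ground truth.

No landmark data ships with the package, so every analysis stage is
exercised on simulated cohorts whose generative parameters are known. The
generator composes three layers:

1. **Motion model** — a canonical lateral-view template of the 12 landmarks
   (pixel units, x anterior, y superior) deformed by per-functional-group
   displacement amplitudes over the swallow: the hyoid moves
   anterior-superior, the larynx elevates, the posterior pharyngeal wall
   shortens the pharynx (moves superiorly), the tongue base retracts
   (posteriorly), and the constrictor coordinates 11/12 collapse anteriorly
   toward the tongue base; the head/neck (vertebral) landmarks stay put. The
   temporal profile is a raised-cosine ramp to a small plateau fraction over
   oral transport, then a raised-cosine pulse peaking mid-pharyngeal-phase.
2. **Per-video nuisance** — one similarity transform per video (uniform
   rotation, scale, translation) modeling head/neck extension, patient
   motion and fluoroscopic magnification. Shared by all raters of a video:
   raters annotate the same recording.
3. **Rater noise** — i.i.d. isotropic Gaussian perturbation per landmark per
   frame plus an optional per-rater bias, modeling annotation error; drawn
   independently per rater and trial.

Randomness is fully determined by (seed, parameters); motion, nuisance and
noise use separate seed streams so changing only the noise leaves the
ground-truth trajectories untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import DegenerateShapeError
from .landmark_model import (
    GROUP_OF_LANDMARK,
    N_LANDMARKS,
    SwallowSeries,
    FrameCoordinates,
    label_phases,
)

#: Canonical lateral-view landmark template (pixels; x anterior, y superior).
#: Invented, anatomically plausible layout: vertebral column (1-5) roughly
#: vertical and posterior, pharyngeal wall and larynx anterior to it.
DEFAULT_TEMPLATE = np.array(
    [
        [60.0, 180.0],  # 1  skull base / upper cervical
        [55.0, 150.0],  # 2  C1 region
        [50.0, 115.0],  # 3  C2 region
        [45.0, 75.0],   # 4  C4 superior
        [42.0, 40.0],   # 5  C4 inferior
        [55.0, 10.0],   # 6  posterior pharyngeal wall (UES level)
        [110.0, 30.0],  # 7  larynx, anterior
        [120.0, 55.0],  # 8  larynx, posterior
        [140.0, 80.0],  # 9  hyoid body
        [120.0, 130.0], # 10 tongue base
        [85.0, 140.0],  # 11 superior constrictor (mandible-base line)
        [80.0, 95.0],   # 12 middle constrictor (greater-horn line)
    ]
)

#: Pharyngeal-phase peak displacement per functional group, pixels (dx, dy).
DEFAULT_GROUP_AMPLITUDES: Mapping[str, tuple[float, float]] = {
    "head_neck_extension": (0.0, 0.0),
    "pharyngeal_shortening": (0.0, 15.0),
    "laryngeal_elevation": (3.0, 14.0),
    "hyoid_movement": (10.0, 12.0),
    "tongue_base_retraction": (-12.0, 2.0),
    "pharyngeal_constriction": (8.0, 2.0),
}


def raised_cosine_pulse(u: np.ndarray) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 pulse on [0, 1], peaking exactly at u = 0.5."""
    return np.sin(np.pi * np.asarray(u)) ** 2


def raised_cosine_ramp(u: np.ndarray) -> np.ndarray:
    """Smooth 0 -> 1 ramp on [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.asarray(u)))


@dataclass(frozen=True)
class MotionModelParams:
    """Template shape and displacement amplitudes of the swallow motion."""

    template: np.ndarray = field(
        default_factory=lambda: DEFAULT_TEMPLATE.copy(), repr=False
    )
    group_amplitudes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_AMPLITUDES)
    )
    oral_fraction: float = 0.15  # plateau amplitude fraction in oral phase
    pulse: Callable[[np.ndarray], np.ndarray] = raised_cosine_pulse

    def __post_init__(self) -> None:
        tpl = np.asarray(self.template, dtype=float)
        if tpl.shape != (N_LANDMARKS, 2) or not np.all(np.isfinite(tpl)):
            raise ValueError("template must be a finite (12, 2) array")
        if np.allclose(tpl, tpl[0]):
            raise DegenerateShapeError("template landmarks coincide")
        object.__setattr__(self, "template", tpl)
        if not 0 <= self.oral_fraction < 1:
            raise ValueError("oral_fraction must be in [0, 1)")

    def amplitude_matrix(self) -> np.ndarray:
        """Per-landmark (12, 2) peak displacement from the group amplitudes."""
        amp = np.zeros((N_LANDMARKS, 2))
        for lm_id, group in GROUP_OF_LANDMARK.items():
            amp[lm_id - 1] = self.group_amplitudes.get(group, (0.0, 0.0))
        return amp


@dataclass(frozen=True)
class RaterNoiseParams:
    """Annotation-error model: isotropic Gaussian sd (pixels) plus bias."""

    sd: float = 2.0
    bias: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class NuisanceParams:
    """Per-video similarity nuisance: patient motion and magnification.

    Rotation is drawn uniformly in ±``rotation_deg`` degrees, scale
    uniformly in ``scale_range``, each translation component uniformly in
    ±``translation_px`` pixels; one draw per video, applied about the
    template centroid to every frame.
    """

    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_px: float = 20.0

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must be positive and ordered")
        if self.rotation_deg < 0 or self.translation_px < 0:
            raise ValueError("nuisance ranges must be non-negative")

    @classmethod
    def zero(cls) -> "NuisanceParams":
        return cls(rotation_deg=0.0, scale_range=(1.0, 1.0), translation_px=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study-scale parameters: 20 videos, two phases, 30 frames/s."""

    n_videos: int = 20
    oral_frames: int = 10
    pharyngeal_frames: int = 21
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_videos, self.oral_frames, self.pharyngeal_frames) < 1:
            raise ValueError("cohort sizes must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless trajectory and generative record for one simulated video."""

    noiseless: SwallowSeries
    profile: np.ndarray = field(repr=False)
    peak_frame: int = 0
    amplitude_scale: float = 1.0
    nuisance_rotation: float = 0.0
    nuisance_scale: float = 1.0
    nuisance_translation: tuple[float, float] = (0.0, 0.0)


def _temporal_profile(
    motion: MotionModelParams, oral_frames: int, pharyngeal_frames: int
) -> tuple[np.ndarray, int]:
    """Per-frame displacement fraction and the index of the pulse peak."""
    f = motion.oral_fraction
    if oral_frames == 1:
        oral = np.array([f])
    else:
        oral = f * raised_cosine_ramp(
            np.arange(oral_frames) / (oral_frames - 1)
        )
    if pharyngeal_frames == 1:
        phar = np.array([1.0])
        peak = oral_frames
    else:
        u = np.arange(pharyngeal_frames) / (pharyngeal_frames - 1)
        # algebraically f + (1-f)*pulse, written so pulse == 1 gives exactly 1.0
        phar = 1.0 - (1.0 - f) * (1.0 - motion.pulse(u))
        peak = oral_frames + int(np.argmax(phar))
    return np.concatenate([oral, phar]), peak


def simulate_swallow(
    motion: MotionModelParams,
    nuisance: NuisanceParams,
    video_id: str,
    oral_frames: int = 10,
    pharyngeal_frames: int = 21,
    frame_rate: float = 30.0,
    seed: int | Sequence[int] = 0,
    amplitude_scale: float = 1.0,
    bolus_label: str = "5 ml thin",
) -> tuple[SwallowSeries, GroundTruth]:
    """Simulate one video's noiseless landmark trajectory.

    Returns the observed series (nuisance applied, phases labeled) and the
    ground truth carrying the nuisance-free trajectory. With zero nuisance
    the peak pharyngeal frame equals ``template + amplitude_scale *
    amplitudes`` exactly (the pulse hits 1.0 on a frame whenever
    ``pharyngeal_frames`` is odd).
    """
    rng = np.random.default_rng(seed)
    amp = amplitude_scale * motion.amplitude_matrix()
    profile, peak = _temporal_profile(motion, oral_frames, pharyngeal_frames)
    truth_coords = motion.template[None] + profile[:, None, None] * amp[None]

    theta = np.deg2rad(rng.uniform(-nuisance.rotation_deg, nuisance.rotation_deg))
    scale = rng.uniform(*nuisance.scale_range)
    shift = rng.uniform(-nuisance.translation_px, nuisance.translation_px, 2)
    if theta == 0.0 and scale == 1.0 and not shift.any():
        observed = truth_coords  # bit-exact when the nuisance is null
    else:
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        center = motion.template.mean(axis=0)
        observed = scale * (truth_coords - center) @ rot.T + center + shift

    n_total = oral_frames + pharyngeal_frames

    def build(coords: np.ndarray) -> SwallowSeries:
        frames = tuple(
            FrameCoordinates(video_id=video_id, frame_index=i, points=coords[i])
            for i in range(n_total)
        )
        series = SwallowSeries(
            video_id=video_id,
            frames=frames,
            frame_rate=frame_rate,
            bolus_label=bolus_label,
        )
        return label_phases(series, 0, oral_frames, n_total)

    truth = GroundTruth(
        noiseless=build(truth_coords),
        profile=profile,
        peak_frame=peak,
        amplitude_scale=amplitude_scale,
        nuisance_rotation=float(theta),
        nuisance_scale=float(scale),
        nuisance_translation=(float(shift[0]), float(shift[1])),
    )
    return build(observed), truth


def simulate_rater_annotations(
    series: SwallowSeries,
    noise: RaterNoiseParams,
    rater_id: str,
    trial_id: str,
    seed: int | Sequence[int] = 0,
) -> SwallowSeries:
    """One rater's annotation of a video: Gaussian jitter plus bias."""
    rng = np.random.default_rng(seed)
    coords = series.as_array()
    if noise.sd > 0:
        coords = coords + rng.normal(0.0, noise.sd, size=coords.shape)
    coords = coords + np.asarray(noise.bias)
    frames = tuple(
        FrameCoordinates(
            video_id=series.video_id,
            frame_index=f.frame_index,
            points=coords[i],
        )
        for i, f in enumerate(series.frames)
    )
    return SwallowSeries(
        video_id=series.video_id,
        frames=frames,
        phases=series.phases,
        frame_rate=series.frame_rate,
        bolus_label=series.bolus_label,
        rater_id=rater_id,
        trial_id=trial_id,
    )


def simulate_cohort(
    cohort: CohortSpec,
    motion: MotionModelParams | None = None,
    nuisance: NuisanceParams | None = None,
    noise: RaterNoiseParams | Mapping[str, RaterNoiseParams] | None = None,
    raters: Sequence[str] = ("R1", "R2"),
    trials: Sequence[str] = ("T1", "T2"),
    amplitude_cv: float = 0.15,
) -> tuple[list[SwallowSeries], dict[str, GroundTruth]]:
    """Simulate a full study: every rater annotates every video twice.

    Per video, the motion (amplitude scale, uniform in ``1 ± amplitude_cv``)
    and the nuisance transform are drawn once and shared across raters and
    trials; rater noise is drawn independently per (video, rater, trial).
    Returns ``n_videos * len(raters) * len(trials)`` series plus the
    per-video ground truth.
    """
    motion = motion or MotionModelParams()
    nuisance = nuisance or NuisanceParams()
    if noise is None:
        noise = RaterNoiseParams()
    if isinstance(noise, RaterNoiseParams):
        noise_by_rater = {r: noise for r in raters}
    else:
        noise_by_rater = dict(noise)
        missing = set(raters) - set(noise_by_rater)
        if missing:
            raise ValueError(f"no noise params for raters {sorted(missing)}")

    series_out: list[SwallowSeries] = []
    truths: dict[str, GroundTruth] = {}
    base = cohort.seed
    for v in range(cohort.n_videos):
        video_id = f"v{v + 1:03d}"
        motion_rng = np.random.default_rng([base, v, 0])
        amp_scale = motion_rng.uniform(1 - amplitude_cv, 1 + amplitude_cv)
        observed, truth = simulate_swallow(
            motion,
            nuisance,
            video_id=video_id,
            oral_frames=cohort.oral_frames,
            pharyngeal_frames=cohort.pharyngeal_frames,
            frame_rate=cohort.frame_rate,
            seed=[base, v, 1],
            amplitude_scale=amp_scale,
        )
        truths[video_id] = truth
        for ri, rater in enumerate(raters):
            for ti, trial in enumerate(trials):
                series_out.append(
                    simulate_rater_annotations(
                        observed,
                        noise_by_rater[rater],
                        rater_id=rater,
                        trial_id=trial,
                        seed=[base, v, 2, ri, ti],
                    )
                )
    return series_out, truths


def ground_truth_to_json(truths: Mapping[str, GroundTruth], sink) -> None:
    """Serialize a ground-truth bundle as JSON (trajectories included)."""
    payload = {
        vid: {
            "peak_frame": t.peak_frame,
            "amplitude_scale": t.amplitude_scale,
            "nuisance": {
                "rotation_rad": t.nuisance_rotation,
                "scale": t.nuisance_scale,
                "translation": list(t.nuisance_translation),
            },
            "profile": t.profile.tolist(),
            "noiseless_coordinates": t.noiseless.as_array().tolist(),
        }
        for vid, t in truths.items()
    }
    json.dump(payload, sink)
    sink.write("\n")
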
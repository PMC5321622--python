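"""The 12-coordinate swallowing landmark scheme and swallow-phase labeling.

Lateral-view videofluoroscopy (modified barium swallow) kinematics are
represented as frame-by-frame constellations of 12 anatomical coordinates.
Coordinates 1-10 are the established scheme mapping head/neck extension,
pharyngeal shortening, laryngeal elevation, hyoid movement and tongue base
retraction; coordinates 11 and 12 locate the superior and middle pharyngeal
constrictors via hard landmarks (base of the mandible, greater horn of the
hyoid).

Canonical coordinate convention throughout the package: x increases
anteriorly, y increases superiorly (anatomical axes). Image-space files with
y increasing downward are flipped at read time by :mod:`casm.tracker_io`.
Frame indices are 0-based; phase intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .exceptions import (
    FrameRangeError,
    MissingPhaseError,
    PhaseOrderingError,
    RegistryError,
)

N_LANDMARKS = 12

FUNCTIONAL_GROUPS = (
    "head_neck_extension",
    "pharyngeal_shortening",
    "laryngeal_elevation",
    "hyoid_movement",
    "tongue_base_retraction",
    "pharyngeal_constriction",
)

PHASES = ("oral_transport", "pharyngeal")

#: landmark id -> functional group of the canonical scheme
GROUP_OF_LANDMARK: Mapping[int, str] = {
    1: "head_neck_extension",
    2: "head_neck_extension",
    3: "head_neck_extension",
    4: "head_neck_extension",
    5: "head_neck_extension",
    6: "pharyngeal_shortening",
    7: "laryngeal_elevation",
    8: "laryngeal_elevation",
    9: "hyoid_movement",
    10: "tongue_base_retraction",
    11: "pharyngeal_constriction",
    12: "pharyngeal_constriction",
}

# Annotation guidance for the two constrictor coordinates: human/synthetic
# rater instructions, not executable logic.
_RULE_11 = (
    "Follow the line formed by the base of the mandible posteriorly to the "
    "pharyngeal wall; place the point where it meets the wall (superior "
    "pharyngeal constrictor). If patient rotation produces a double "
    "mandibular shadow, use the superior shadow."
)
_RULE_12 = (
    "Follow the line coextensive with the greater horn of the hyoid bone "
    "posteriorly to the pharyngeal wall; place the point where it meets the "
    "wall (middle pharyngeal constrictor)."
)

_DEFAULT_NAMES: Mapping[int, str] = {
    1: "head_neck_1",
    2: "head_neck_2",
    3: "head_neck_3",
    4: "head_neck_4",
    5: "head_neck_5",
    6: "posterior_pharyngeal_wall",
    7: "larynx_anterior",
    8: "larynx_posterior",
    9: "hyoid_body",
    10: "tongue_base",
    11: "superior_constrictor",
    12: "middle_constrictor",
}


@dataclass(frozen=True)
class LandmarkDefinition:
    """One tracked coordinate: id, label, functional group, annotation rule."""

    id: int
    name: str
    functional_group: str
    annotation_rule: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.id <= N_LANDMARKS):
            raise RegistryError(f"landmark id must be in 1..12, got {self.id}")
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise RegistryError(
                f"unknown functional group {self.functional_group!r}"
            )


@dataclass(frozen=True)
class LandmarkRegistry:
    """Ordered scheme of exactly 12 landmarks with ids 1..12."""

    landmarks: tuple[LandmarkDefinition, ...]

    def __post_init__(self) -> None:
        ids = [lm.id for lm in self.landmarks]
        if ids != list(range(1, N_LANDMARKS + 1)):
            raise RegistryError(
                f"registry must hold ids 1..12 ascending, got {ids}"
            )

    def __len__(self) -> int:
        return len(self.landmarks)

    def __iter__(self) -> Iterator[LandmarkDefinition]:
        return iter(self.landmarks)

    def __getitem__(self, landmark_id: int) -> LandmarkDefinition:
        if not (1 <= landmark_id <= len(self.landmarks)):
            raise RegistryError(f"no landmark with id {landmark_id}")
        return self.landmarks[landmark_id - 1]

    def group_members(self, functional_group: str) -> tuple[int, ...]:
        """Landmark ids belonging to ``functional_group`` (ascending)."""
        from .exceptions import GroupError

        if functional_group not in FUNCTIONAL_GROUPS:
            raise GroupError(functional_group)
        return tuple(
            lm.id for lm in self.landmarks
            if lm.functional_group == functional_group
        )

    def groups(self) -> dict[str, tuple[int, ...]]:
        """Mapping functional group -> member ids."""
        return {g: self.group_members(g) for g in FUNCTIONAL_GROUPS}


def default_registry(
    names: Mapping[int, str] | None = None,
) -> LandmarkRegistry:
    """The canonical 12-landmark registry.

    Functional groups follow the standard scheme (head/neck extension 1-5,
    pharyngeal shortening 6, laryngeal elevation 7-8, hyoid movement 9,
    tongue base retraction 10, pharyngeal constriction 11-12). The anatomical
    names of landmarks 1-10 are placeholders overridable via ``names``; 11
    and 12 carry their annotation rules.

    Parameters
    ----------
    names
        Optional overrides, landmark id -> display name.
    """
    names = {**_DEFAULT_NAMES, **(names or {})}
    rules = {11: _RULE_11, 12: _RULE_12}
    return LandmarkRegistry(
        tuple(
            LandmarkDefinition(
                id=i,
                name=names[i],
                functional_group=GROUP_OF_LANDMARK[i],
                annotation_rule=rules.get(i, ""),
            )
            for i in range(1, N_LANDMARKS + 1)
        )
    )


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape != (N_LANDMARKS, 2):
        raise ValueError(
            f"expected {N_LANDMARKS} (x, y) pairs, got array of shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise ValueError("landmark coordinates must be finite")
    return pts


@dataclass(frozen=True)
class FrameCoordinates:
    """All 12 landmark positions in one video frame (canonical axes)."""

    video_id: str
    frame_index: int
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        object.__setattr__(self, "points", _as_points(self.points))


@dataclass(frozen=True)
class PhaseInterval:
    """Half-open frame interval [onset, offset) labeled with a swallow phase."""

    phase: str
    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not self.onset_frame < self.offset_frame:
            raise PhaseOrderingError(
                f"phase interval empty or reversed: "
                f"[{self.onset_frame}, {self.offset_frame})"
            )

    def __contains__(self, frame_index: int) -> bool:
        return self.onset_frame <= frame_index < self.offset_frame

    def __len__(self) -> int:
        return self.offset_frame - self.onset_frame


@dataclass(frozen=True)
class SwallowSeries:
    """One video's frame-by-frame landmark trajectory plus phase labels.

    ``frames`` are ordered with strictly increasing ``frame_index``; every
    phase interval must lie within ``[first_frame, last_frame + 1]``.
    """

    video_id: str
    frames: tuple[FrameCoordinates, ...]
    phases: tuple[PhaseInterval, ...] = ()
    frame_rate: float = 30.0
    bolus_label: str = ""
    rater_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        object.__setattr__(self, "phases", tuple(self.phases))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")
        for iv in self.phases:
            self._check_in_range(iv)
        for a, b in zip(self.phases, self.phases[1:]):
            if b.onset_frame < a.offset_frame:
                raise PhaseOrderingError(
                    f"phase intervals overlap: {a} and {b}"
                )

    def _check_in_range(self, interval: PhaseInterval) -> None:
        if not self.frames:
            raise FrameRangeError("cannot label phases on an empty series")
        lo = self.frames[0].frame_index
        hi = self.frames[-1].frame_index + 1
        if interval.onset_frame < lo or interval.offset_frame > hi:
            raise FrameRangeError(
                f"interval [{interval.onset_frame}, {interval.offset_frame}) "
                f"outside series frame range [{lo}, {hi})"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=int)

    def as_array(self) -> np.ndarray:
        """Coordinates as an ``(n_frames, 12, 2)`` float array."""
        return np.stack([f.points for f in self.frames]) if self.frames else (
            np.empty((0, N_LANDMARKS, 2))
        )

    def phase_interval(self, phase: str) -> PhaseInterval:
        for iv in self.phases:
            if iv.phase == phase:
                return iv
        raise MissingPhaseError(phase)


def label_phases(
    series: SwallowSeries,
    oral_onset: int,
    pharyngeal_onset: int,
    pharyngeal_offset: int,
) -> SwallowSeries:
    """Attach oral-transport and pharyngeal phase intervals to a series.

    Oral transport runs ``[oral_onset, pharyngeal_onset)`` — the frame
    preceding pharyngeal onset ends oral transport. The pharyngeal phase
    starts at the first frame of rapid anterior-superior hyoid movement and
    runs ``[pharyngeal_onset, pharyngeal_offset)``, the offset marking
    closure of the upper esophageal sphincter.
    """
    if not (oral_onset < pharyngeal_onset < pharyngeal_offset):
        raise PhaseOrderingError(
            "need oral_onset < pharyngeal_onset < pharyngeal_offset, got "
            f"{oral_onset}, {pharyngeal_onset}, {pharyngeal_offset}"
        )
    intervals = (
        PhaseInterval("oral_transport", oral_onset, pharyngeal_onset),
        PhaseInterval("pharyngeal", pharyngeal_onset, pharyngeal_offset),
    )
    # replace() re-runs validation, raising FrameRangeError if out of range
    return replace(series, phases=intervals)


def frames_in_phase(
    series: SwallowSeries, phase: str
) -> list[FrameCoordinates]:
    """Frames whose index lies in the named phase's interval, in order."""
    interval = series.phase_interval(phase)
    return [f for f in series.frames if f.frame_index in interval]


def phase_of_frame(series: SwallowSeries, frame_index: int) -> str | None:
    """Phase name covering ``frame_index``, or None if unlabeled."""
    for iv in series.phases:
        if frame_index in iv:
            return iv.phase
    return None
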
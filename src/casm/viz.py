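"""Shape-change vector plots: consensus landmarks with displacement arrows.

Renders the standard morphometric visualization of a discriminant axis: the
consensus configuration's 12 landmarks with one arrow per landmark showing
its displacement along the axis (anchored to the vertebral-column
reference), magnified for legibility. Output is written as vector graphics
(SVG) and is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .exceptions import ShapeMismatchError
from .landmark_model import LandmarkRegistry
from .procrustes import Shape
from .shape_stats import AnchoredVectors

_GROUP_COLORS = {
    "head_neck_extension": "#4c72b0",
    "pharyngeal_shortening": "#dd8452",
    "laryngeal_elevation": "#55a868",
    "hyoid_movement": "#c44e52",
    "tongue_base_retraction": "#8172b3",
    "pharyngeal_constriction": "#937860",
}


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options for the shape-change plot."""

    magnification: float = 3.0
    show_labels: bool = True
    anterior_left: bool = True
    format: str = "svg"

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")


@dataclass(frozen=True)
class RenderSummary:
    """What was drawn: counts and arrow geometry, for programmatic checks."""

    n_points: int
    n_arrows: int
    arrow_lengths: np.ndarray
    orientation: str


def render_shape_change(
    consensus: Shape,
    vectors: AnchoredVectors | np.ndarray,
    spec: PlotSpec = PlotSpec(),
    sink=None,
    registry: LandmarkRegistry | None = None,
) -> RenderSummary:
    """Draw the consensus shape with per-landmark displacement arrows.

    Each landmark is one point and one arrow whose drawn length is
    ``magnification * |displacement|``. Orientation follows the lateral-view
    convention: superior up and (by default) anterior to the viewer's left;
    the orientation is stated in the figure legend. Writes SVG (or the
    format named in ``spec``) to ``sink`` when given and returns a
    :class:`RenderSummary`.
    """
    cons = np.asarray(consensus, dtype=float)
    if isinstance(vectors, AnchoredVectors):
        reference = vectors.reference_group
        vecs = vectors.vectors
    else:
        reference = None
        vecs = np.asarray(vectors, dtype=float)
    if cons.ndim != 2 or cons.shape[1] != 2:
        raise ShapeMismatchError(f"consensus must be (k, 2), got {cons.shape}")
    if vecs.shape != cons.shape:
        raise ShapeMismatchError(
            f"vectors shape {vecs.shape} != consensus shape {cons.shape}"
        )

    tips = cons + spec.magnification * vecs
    lengths = spec.magnification * np.linalg.norm(vecs, axis=1)

    fig, ax = plt.subplots(figsize=(5, 5))
    try:
        for i in range(cons.shape[0]):
            lm_id = i + 1
            color = "#333333"
            if registry is not None:
                color = _GROUP_COLORS.get(
                    registry[lm_id].functional_group, color
                )
            pt = ax.scatter(
                cons[i, 0], cons[i, 1], s=30, color=color, zorder=3
            )
            pt.set_gid(f"landmark-point-{lm_id}")
            arrow = ax.annotate(
                "",
                xy=tuple(tips[i]),
                xytext=tuple(cons[i]),
                arrowprops={
                    "arrowstyle": "->",
                    "color": color,
                    "shrinkA": 0,
                    "shrinkB": 0,
                },
            )
            arrow.arrow_patch.set_gid(f"landmark-arrow-{lm_id}")
            if spec.show_labels:
                ax.annotate(
                    str(lm_id),
                    cons[i],
                    textcoords="offset points",
                    xytext=(4, 4),
                    fontsize=8,
                )
        ax.set_aspect("equal")
        ax.margins(0.15)
        if spec.anterior_left:
            ax.invert_xaxis()
            orientation = "superior up, anterior left"
        else:
            orientation = "superior up, anterior right"
        ax.set_title(
            f"Shape change ({spec.magnification:g}x arrows)"
            + (f", anchored to {reference}" if reference else "")
        )
        ax.set_xlabel(orientation)
        ax.set_xticks([])
        ax.set_yticks([])
        if sink is not None:
            # fixed hashsalt + no date metadata -> byte-identical repeat renders
            with matplotlib.rc_context({"svg.hashsalt": "casm"}):
                fig.savefig(
                    sink,
                    format=spec.format,
                    metadata={"Date": None} if spec.format == "svg" else None,
                )
    finally:
        plt.close(fig)
    return RenderSummary(
        n_points=cons.shape[0],
        n_arrows=vecs.shape[0],
        arrow_lengths=lengths,
        orientation=orientation,
    )
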
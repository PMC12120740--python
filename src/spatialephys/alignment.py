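"""Landmark-based alignment of transcriptomic spots onto the electrode frame.

The two modalities image the same tissue at different scales and
orientations.  Two homologous anatomical reference points are placed in each
frame — ``i``/``k`` at the dentate-gyrus crest midpoint and ``j``/``l`` on
the DG supra-blade edge.  Alignment is a similarity transform (scale +
rotation + translation, no shear): the scale is the landmark-distance ratio
after converting each frame to micrometres with its physical anchor (55 µm
spots / 42 µm electrode pitch), the rotation is the difference between the
angles each landmark pair subtends against the horizontal through the fused
point ``m`` (theta = theta_ephys - theta_srt), and the translation fuses
``i`` with ``k``.  The residual distance between the transformed second
landmark and ``l`` is reported as an alignment quality metric rather than
absorbed by a shear term.

Electrodes are then fractionally matched to spots by distance: an electrode
belongs to every spot whose centre lies within ``r_assign`` (default spot
radius + half pitch), with uniform weights among a spot's electrodes, and
spot-level electrophysiological features are weight-averaged over matched
electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datatypes import PipelineError, ValidationError

FEATURE_COLUMNS = (
    "lfp_rate",
    "amplitude",
    "energy",
    "event_delay",
    "positive_peaks",
    "negative_peaks",
)


@dataclass(frozen=True)
class LandmarkSet:
    """Homologous reference points: ``i``, ``j`` in the spot (SRT) frame,
    ``k``, ``l`` in the electrode frame, in each frame's native units."""

    i: tuple[float, float]
    j: tuple[float, float]
    k: tuple[float, float]
    l: tuple[float, float]  # noqa: E741 - paper's landmark naming

    def __post_init__(self) -> None:
        for name in "ijkl":
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {name} must be a finite 2-vector")
        if np.allclose(self.i, self.j) or np.allclose(self.k, self.l):
            raise ValidationError("coincident landmarks give degenerate geometry")


@dataclass
class AlignmentTransform:
    """Similarity transform mapping spot-frame points into the fused
    electrode frame: ``p -> scale * R(theta) @ (p - i) + k`` (µm).

    ``theta`` is the final rotation angle (CCW radians, wrapped to
    (-pi, pi]); ``scale`` the unitless frame ratio; ``m``/``n`` the fused
    reference points; ``x, y, x_prime, y_prime`` the signed landmark
    offsets defining ``theta_srt``/``theta_ephys``; ``residual`` the
    relative mismatch ``|T(j) - l| / |l - k|``.
    """

    scale: float
    theta: float
    translation: np.ndarray
    pivot: np.ndarray
    m: np.ndarray = field(default=None)  # type: ignore[assignment]
    n: np.ndarray = field(default=None)  # type: ignore[assignment]
    x: float = 0.0
    y: float = 0.0
    x_prime: float = 0.0
    y_prime: float = 0.0
    theta_srt: float = 0.0
    theta_ephys: float = 0.0
    residual: float = 0.0

    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def inverse(self) -> "AlignmentTransform":
        inv = AlignmentTransform(
            scale=1.0 / self.scale,
            theta=_wrap_angle(-self.theta),
            translation=np.asarray(self.pivot, dtype=float),
            pivot=np.asarray(self.translation, dtype=float),
        )
        return inv


def _wrap_angle(theta: float) -> float:
    """Wrap to (-pi, pi]."""
    wrapped = (theta + np.pi) % (2 * np.pi) - np.pi
    if wrapped == -np.pi:
        wrapped = np.pi
    return float(wrapped)


def compute_alignment(
    landmarks: LandmarkSet,
    srt_scale_um_per_unit: float = 1.0,
    ephys_scale_um_per_unit: float = 1.0,
) -> AlignmentTransform:
    """Derive the similarity transform from two homologous landmark pairs.

    Each frame is first put in micrometres via its physical anchor scale
    (µm per native coordinate unit).  The overall scale is then the ratio
    of the landmark separations, so a residual unit mismatch between the
    anchors is absorbed and ``T(j)`` lands on ``l`` exactly for consistent
    landmarks.

    The rotation follows the horizontal/vertical intersection-line
    construction: with the frames translated so ``i`` and ``k`` coincide at
    the fused point ``m``, ``x``/``y`` are the offsets of ``j`` from the
    horizontal line through ``m`` (and ``x'``/``y'`` those of ``l``), giving
    ``theta_srt = atan2(y, x)``, ``theta_ephys = atan2(y', x')`` and the
    final angle ``theta = theta_ephys - theta_srt``.
    """
    if srt_scale_um_per_unit <= 0 or ephys_scale_um_per_unit <= 0:
        raise ValidationError("scale anchors must be positive")
    i = np.asarray(landmarks.i, dtype=float) * srt_scale_um_per_unit
    j = np.asarray(landmarks.j, dtype=float) * srt_scale_um_per_unit
    k = np.asarray(landmarks.k, dtype=float) * ephys_scale_um_per_unit
    l = np.asarray(landmarks.l, dtype=float) * ephys_scale_um_per_unit  # noqa: E741

    d_srt = np.linalg.norm(j - i)
    d_ephys = np.linalg.norm(l - k)
    if d_srt == 0 or d_ephys == 0:
        raise ValidationError("coincident landmarks give degenerate geometry")
    scale = d_ephys / d_srt

    x, y = (j - i)  # offsets from the horizontal through the fused point m
    x_p, y_p = (l - k)
    theta_srt = float(np.arctan2(y, x))
    theta_ephys = float(np.arctan2(y_p, x_p))
    theta = _wrap_angle(theta_ephys - theta_srt)

    tf = AlignmentTransform(
        scale=float(scale),
        theta=theta,
        translation=k,
        pivot=i,
        x=float(x),
        y=float(y),
        x_prime=float(x_p),
        y_prime=float(y_p),
        theta_srt=theta_srt,
        theta_ephys=theta_ephys,
    )
    tj = apply_transform(j[None, :], tf)[0]
    tf.m = k.copy()
    tf.n = 0.5 * (tj + l)
    tf.residual = float(np.linalg.norm(tj - l) / d_ephys)
    return tf


def apply_transform(points: np.ndarray, transform: AlignmentTransform) -> np.ndarray:
    """Map ``points`` (N x 2) through ``scale * R(theta) @ (p - pivot) + t``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centered = pts - np.asarray(transform.pivot, dtype=float)
    rotated = centered @ transform.rotation_matrix().T
    return transform.scale * rotated + np.asarray(transform.translation, dtype=float)


def invert_transform(points: np.ndarray, transform: AlignmentTransform) -> np.ndarray:
    """Exact algebraic inverse of :func:`apply_transform`."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centered = (pts - np.asarray(transform.translation, dtype=float)) / transform.scale
    c, s = np.cos(-transform.theta), np.sin(-transform.theta)
    rot = np.array([[c, -s], [s, c]])
    return centered @ rot.T + np.asarray(transform.pivot, dtype=float)


@dataclass
class SpotElectrodeMap:
    """Fractional spot -> electrode assignment.

    ``assignments`` maps each matched spot barcode to a list of
    ``(electrode_id, weight)`` with weights summing to one; spots with no
    electrode within reach and electrodes serving no spot are listed
    separately.
    """

    assignments: dict[str, list[tuple[str, float]]]
    unmatched_spots: list[str]
    unmatched_electrodes: list[str]
    r_assign: float


def match_spots_to_electrodes(
    spot_ids: list[str],
    spot_xy: np.ndarray,
    spot_diameter: float,
    electrode_ids: list[str],
    electrode_xy: np.ndarray,
    pitch: float = 42.0,
    r_assign: float | None = None,
) -> SpotElectrodeMap:
    """Assign electrodes to spots by centre distance in the fused frame.

    An electrode belongs to a spot when its centre lies within ``r_assign``
    of the spot centre; the default ``spot_diameter/2 + pitch/2`` counts
    electrodes whose footprint touches the spot disc.  Weights are uniform
    over a spot's electrodes; one electrode may serve several spots.
    """
    electrode_xy = np.atleast_2d(np.asarray(electrode_xy, dtype=float))
    spot_xy = np.atleast_2d(np.asarray(spot_xy, dtype=float))
    if electrode_xy.shape[0] == 0:
        raise PipelineError("no electrodes available for matching")
    if r_assign is None:
        r_assign = spot_diameter / 2.0 + pitch / 2.0
    tree = cKDTree(electrode_xy)
    neighbour_lists = tree.query_ball_point(spot_xy, r=r_assign)
    assignments: dict[str, list[tuple[str, float]]] = {}
    unmatched_spots: list[str] = []
    used: set[int] = set()
    for sid, neighbours in zip(spot_ids, neighbour_lists):
        if not neighbours:
            unmatched_spots.append(sid)
            continue
        w = 1.0 / len(neighbours)
        assignments[sid] = [(electrode_ids[e], w) for e in sorted(neighbours)]
        used.update(neighbours)
    unmatched_electrodes = [
        electrode_ids[e] for e in range(len(electrode_ids)) if e not in used
    ]
    return SpotElectrodeMap(
        assignments=assignments,
        unmatched_spots=unmatched_spots,
        unmatched_electrodes=unmatched_electrodes,
        r_assign=float(r_assign),
    )


def aggregate_features_per_spot(
    spot_map: SpotElectrodeMap,
    features: pd.DataFrame,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Weight-average electrode features onto spots.

    ``features`` is indexed by electrode id.  Missing (NaN) electrode
    values are excluded from that spot's mean with the remaining weights
    renormalised; spots with no matched electrode carry NaN throughout.
    """
    cols = [c for c in feature_columns if c in features.columns]
    all_spots = list(spot_map.assignments) + spot_map.unmatched_spots
    out = pd.DataFrame(index=pd.Index(all_spots, name="spot"), columns=cols, dtype=float)
    for sid, pairs in spot_map.assignments.items():
        ids = [e for e, _ in pairs]
        w = np.array([wt for _, wt in pairs], dtype=float)
        sub = features.reindex(ids)[cols].to_numpy(dtype=float)
        for c_idx, c in enumerate(cols):
            vals = sub[:, c_idx]
            ok = np.isfinite(vals)
            if not ok.any():
                continue
            ww = w[ok] / w[ok].sum()
            out.loc[sid, c] = float(vals[ok] @ ww)
    return out
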
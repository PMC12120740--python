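"""Core in-memory containers shared across the pipeline.

All spatial coordinates are Cartesian micrometres with the origin at the
lower-left corner of the array/slide, x increasing rightward and y upward.
Angles are counter-clockwise radians. Time is seconds, amplitude microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Region labels recognised for hippocampal-cortical slices.
REGIONS = ("DG", "Hilus", "CA1", "CA3", "EC", "PC", "none")

#: Required columns of an event table (full dialect).
EVENT_COLUMNS = (
    "electrode_id",
    "time",
    "amplitude",
    "positive_peaks",
    "negative_peaks",
    "energy",
)


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class PipelineError(RuntimeError):
    """Raised when a processing stage cannot produce a usable result."""


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """Geometry of a rectangular microelectrode array.

    Electrode ids run row-major from 0 at the lower-left corner; the
    electrode centre of id ``r * cols + c`` sits at ``(c * pitch, r * pitch)``
    micrometres.

    Parameters
    ----------
    rows, cols
        Array dimensions (default 64 x 64, i.e. 4096 electrodes).
    pitch
        Centre-to-centre electrode spacing in micrometres (default 42).
    electrode_size
        Electrode side length in micrometres (default 21).
    origin
        Tag recording the coordinate convention; only ``"lower-left"`` is
        produced by this package.
    """

    rows: int = 64
    cols: int = 64
    pitch: float = 42.0
    electrode_size: float = 21.0
    origin: str = "lower-left"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("array must have at least one electrode")
        if not (self.pitch > self.electrode_size > 0):
            raise ValidationError(
                f"need pitch > electrode_size > 0, got pitch={self.pitch}, "
                f"electrode_size={self.electrode_size}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    def electrode_xy(self, ids: np.ndarray | None = None) -> np.ndarray:
        """Centre coordinates (µm) for the given integer ids (default: all)."""
        if ids is None:
            ids = np.arange(self.n_electrodes)
        ids = np.asarray(ids, dtype=int)
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_electrodes):
            raise ValidationError("electrode id outside array")
        r, c = np.divmod(ids, self.cols)
        return np.column_stack([c * self.pitch, r * self.pitch]).astype(float)

    def contains_id(self, electrode_id: int) -> bool:
        return 0 <= int(electrode_id) < self.n_electrodes


@dataclass
class ExpressionMatrix:
    """Gene x spot expression with spot geometry and region labels.

    ``counts`` is dense ``|genes| x |spots|`` and non-negative; raw on read
    (``normalized=False``) and scaled to a common per-spot total after
    :func:`spatialephys.association.normalize_total_counts`.
    """

    genes: list[str]
    spots: list[str]
    counts: np.ndarray
    spot_xy: np.ndarray
    region: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.spot_xy = np.asarray(self.spot_xy, dtype=float)
        n_g, n_s = len(self.genes), len(self.spots)
        if self.counts.shape != (n_g, n_s):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({n_g}, {n_s})"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("negative expression value")
        if len(set(self.spots)) != n_s:
            raise ValidationError("spot barcodes not unique")
        if self.spot_xy.shape != (n_s, 2):
            raise ValidationError("every spot needs planar coordinates")
        if len(self.region) != n_s:
            raise ValidationError("one region label per spot required")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def subset_spots(self, keep: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to a boolean/index spot selection."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            genes=list(self.genes),
            spots=[self.spots[i] for i in keep],
            counts=self.counts[:, keep].copy(),
            spot_xy=self.spot_xy[keep].copy(),
            region=[self.region[i] for i in keep],
            normalized=self.normalized,
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            genes=[self.genes[i] for i in keep],
            spots=list(self.spots),
            counts=self.counts[keep, :].copy(),
            spot_xy=self.spot_xy.copy(),
            region=list(self.region),
            normalized=self.normalized,
        )

    def gene_index(self, symbols: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in symbols if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in symbols], dtype=int)


@dataclass
class LFPEventTable:
    """Detected LFP events for one recording.

    ``events`` holds one row per event with columns
    ``electrode_id`` (string id), ``time`` (s), ``amplitude`` (µV),
    ``positive_peaks``, ``negative_peaks`` (counts) and ``energy`` (a.u.).
    Missing feature columns are NaN, never silently zero.
    """

    events: pd.DataFrame
    duration: float
    array_spec: ElectrodeArraySpec = field(default_factory=ElectrodeArraySpec)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("recording duration must be positive")
        ev = self.events.copy()
        for col in EVENT_COLUMNS:
            if col not in ev.columns:
                ev[col] = np.nan
        ev["electrode_id"] = ev["electrode_id"].astype(str)
        ev = ev[list(EVENT_COLUMNS)]
        for col in EVENT_COLUMNS[1:]:
            ev[col] = ev[col].astype(float)
        if len(ev):
            t = ev["time"].to_numpy(dtype=float)
            if np.any(t < 0) or np.any(t > self.duration):
                raise ValidationError("event time outside [0, duration]")
            ids = ev["electrode_id"].to_numpy()
            numeric = pd.to_numeric(pd.Series(ids), errors="coerce")
            bad = [
                i for i, v in zip(ids, numeric)
                if np.isfinite(v) and not self.array_spec.contains_id(int(v))
            ]
            if bad:
                raise ValidationError(f"electrode ids outside array: {bad[:5]}")
            for col in ("positive_peaks", "negative_peaks"):
                v = ev[col].to_numpy(dtype=float)
                if np.any(v[np.isfinite(v)] < 0):
                    raise ValidationError(f"negative {col}")
            ev = ev.sort_values(["electrode_id", "time"], kind="mergesort")
            ev = ev.reset_index(drop=True)
        self.events = ev

    @property
    def n_events(self) -> int:
        return len(self.events)

    def electrode_ids(self) -> list[str]:
        return sorted(self.events["electrode_id"].unique())

    def counts_per_electrode(self) -> pd.Series:
        return self.events.groupby("electrode_id").size()

    def subset_electrodes(self, keep_ids: set[str]) -> "LFPEventTable":
        mask = self.events["electrode_id"].isin(keep_ids)
        return replace(self, events=self.events[mask].reset_index(drop=True))
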
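"""LFP event detection and per-electrode network-activity features.

Traces are band-limited with a zero-phase fourth-order Butterworth filter
(1-100 Hz by default, matching the slow-oscillation band recorded from
hippocampal slices), events are taken at local extrema exceeding a hard
threshold of ``threshold_sigma`` robust standard deviations (median absolute
deviation / 0.6745), spuriously firing electrodes are removed by quantile
thresholding of per-electrode event counts, and each retained electrode is
summarised by six features: LFP rate (events/s), mean absolute event
amplitude (µV), event energy (a.u.), LFP event delay relative to network
event onsets (s), and positive/negative peak counts per event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import LFPEventTable, PipelineError, ValidationError

MAD_TO_SIGMA = 0.6745  # MAD of a Gaussian = 0.6745 sigma


def bandpass_filter(
    trace: np.ndarray,
    low_hz: float = 1.0,
    high_hz: float = 100.0,
    order: int = 4,
    fs: float = 14_000.0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length.

    Forward-backward application preserves event timing at the cost of
    squaring the single-pass magnitude response.
    """
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={fs / 2}) Hz"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return trace
    return signal.sosfiltfilt(sos, trace)


@dataclass
class DetectedEvent:
    """One detected LFP event with its ±window summary features."""

    time: float
    amplitude: float
    positive_peaks: int
    negative_peaks: int
    energy: float
    sample: int


def robust_sigma(trace: np.ndarray) -> float:
    """Noise scale via the median absolute deviation, MAD / 0.6745."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return 0.0
    return float(np.median(np.abs(trace - np.median(trace))) / MAD_TO_SIGMA)


def detect_lfp_events(
    trace: np.ndarray,
    fs: float,
    threshold_sigma: float = 5.0,
    min_separation_ms: float = 20.0,
    window_ms: float = 100.0,
) -> list[DetectedEvent]:
    """Hard-threshold detection of LFP events on a band-limited trace.

    Events are local extrema of ``|trace|`` exceeding
    ``threshold_sigma * robust_sigma(trace)``; extrema closer than
    ``min_separation_ms`` are merged keeping the larger one.  Amplitude is
    the signed extremum value, positive/negative peak counts and energy
    (sum of squared samples) are measured over ±``window_ms`` around it.
    """
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    if threshold_sigma <= 0:
        raise ValueError("threshold_sigma must be positive")
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return []
    sigma = robust_sigma(trace)
    if sigma == 0.0:
        # sparse-signal trace (e.g. noiseless planted templates): the MAD
        # collapses to zero, fall back to the standard deviation
        sigma = float(trace.std())
    if sigma == 0.0:
        return []
    threshold = threshold_sigma * sigma
    min_sep = max(int(round(min_separation_ms * 1e-3 * fs)), 1)
    peaks, props = signal.find_peaks(np.abs(trace), height=threshold, distance=min_sep)
    # a second merge pass: find_peaks' distance already keeps the larger of
    # close peaks, but be explicit for peaks at exactly the boundary
    events: list[DetectedEvent] = []
    half = int(round(window_ms * 1e-3 * fs))
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, trace.size)
        seg = trace[lo:hi]
        pos, _ = signal.find_peaks(seg, height=threshold)
        neg, _ = signal.find_peaks(-seg, height=threshold)
        events.append(
            DetectedEvent(
                time=float(p / fs),
                amplitude=float(trace[p]),
                positive_peaks=int(pos.size),
                negative_peaks=int(neg.size),
                energy=float(np.sum(seg**2)),
                sample=int(p),
            )
        )
    return events


def events_to_table(
    per_electrode: dict[str, list[DetectedEvent]],
    duration: float,
    array_spec,
) -> LFPEventTable:
    """Assemble detector output into an :class:`LFPEventTable`."""
    rows = [
        {
            "electrode_id": eid,
            "time": ev.time,
            "amplitude": ev.amplitude,
            "positive_peaks": ev.positive_peaks,
            "negative_peaks": ev.negative_peaks,
            "energy": ev.energy,
        }
        for eid, evs in per_electrode.items()
        for ev in evs
    ]
    return LFPEventTable(
        events=pd.DataFrame(
            rows,
            columns=[
                "electrode_id",
                "time",
                "amplitude",
                "positive_peaks",
                "negative_peaks",
                "energy",
            ],
        ),
        duration=duration,
        array_spec=array_spec,
    )


def remove_spurious_electrodes(
    table: LFPEventTable,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
) -> tuple[LFPEventTable, list[str]]:
    """Drop electrodes whose event count falls outside the [lower_q, upper_q]
    quantiles of the per-electrode count distribution.

    Returns the filtered table and the list of dropped electrode ids.
    """
    if not (0 <= lower_q < upper_q <= 1):
        raise ValueError("need 0 <= lower_q < upper_q <= 1")
    counts = table.counts_per_electrode()
    if counts.empty:
        return table, []
    lo = counts.quantile(lower_q)
    hi = counts.quantile(upper_q)
    keep = counts[(counts >= lo) & (counts <= hi)].index
    dropped = sorted(set(counts.index) - set(keep))
    if len(keep) == 0:
        raise PipelineError(
            f"quantile filter ({lower_q}, {upper_q}) removed every electrode; "
            f"count range {counts.min()}-{counts.max()}"
        )
    return table.subset_electrodes(set(keep)), dropped


def network_event_onsets(
    table: LFPEventTable,
    window_s: float = 0.01,
    threshold_sd: float = 3.0,
) -> pd.DataFrame:
    """Detect network-wide event epochs from the population event rate.

    The pooled event times are binned into ``window_s`` windows; epochs are
    maximal runs where the windowed population rate exceeds
    ``mean + threshold_sd * SD``.  Returns a frame with ``onset`` and
    ``offset`` times (s), one row per network event.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    times = table.events["time"].to_numpy(dtype=float)
    n_bins = max(int(np.ceil(table.duration / window_s)), 1)
    hist, edges = np.histogram(times, bins=n_bins, range=(0.0, n_bins * window_s))
    thresh = hist.mean() + threshold_sd * hist.std()
    above = hist > thresh
    onsets, offsets = [], []
    in_run = False
    for b, flag in enumerate(above):
        if flag and not in_run:
            onsets.append(edges[b])
            in_run = True
        elif not flag and in_run:
            offsets.append(edges[b])
            in_run = False
    if in_run:
        offsets.append(edges[-1])
    return pd.DataFrame({"onset": onsets, "offset": offsets})


def compute_electrode_features(
    table: LFPEventTable,
    network_onsets: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-electrode mean activity features, indexed by electrode id.

    ``lfp_rate`` = event count / duration; ``amplitude`` is the mean
    absolute event amplitude; ``energy``, ``positive_peaks`` and
    ``negative_peaks`` are event means; ``event_delay`` is the mean, over
    network events, of the latency from onset to the electrode's first
    following event (electrodes silent during a network event contribute
    nothing to its mean; NaN when onsets are absent or never matched).
    Electrode coordinates (µm) are attached from the array spec when the
    ids are integers on the grid.
    """
    ev = table.events
    ids = sorted(ev["electrode_id"].unique())
    feats = pd.DataFrame(index=pd.Index(ids, name="electrode_id"))
    grouped = ev.groupby("electrode_id")
    feats["lfp_rate"] = grouped.size() / table.duration
    feats["amplitude"] = grouped["amplitude"].apply(lambda a: np.abs(a).mean())
    feats["energy"] = grouped["energy"].mean()
    feats["positive_peaks"] = grouped["positive_peaks"].mean()
    feats["negative_peaks"] = grouped["negative_peaks"].mean()

    delays = pd.Series(np.nan, index=feats.index)
    if network_onsets is not None and len(network_onsets):
        onset_arr = network_onsets["onset"].to_numpy(dtype=float)
        offset_arr = network_onsets["offset"].to_numpy(dtype=float)
        for eid, sub in grouped:
            t = np.sort(sub["time"].to_numpy(dtype=float))
            per_event = []
            for onset, offset in zip(onset_arr, offset_arr):
                idx = np.searchsorted(t, onset, side="left")
                if idx < t.size and t[idx] <= offset:
                    per_event.append(t[idx] - onset)
            if per_event:
                delays[eid] = float(np.mean(per_event))
    feats["event_delay"] = delays

    try:
        int_ids = np.array([int(i) for i in ids])
        xy = table.array_spec.electrode_xy(int_ids)
        feats["x_um"], feats["y_um"] = xy[:, 0], xy[:, 1]
    except (ValueError, ValidationError):
        pass  # non-grid ids: caller supplies coordinates separately
    return feats


@dataclass
class WaveformClassification:
    labels: np.ndarray
    pca_coords: np.ndarray
    silhouette: float | None
    degenerate: bool


def classify_waveforms(
    waveforms: np.ndarray,
    n_clusters: int,
    n_components: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> WaveformClassification:
    """PCA + k-means clustering of event waveform shapes.

    Waveforms (rows, equal length) are projected on the leading
    ``n_components`` principal components and partitioned with k-means
    (fixed seed, ``n_init`` restarts).  The silhouette score is reported
    as a label-permutation-invariant quality metric; identical waveforms
    make it undefined and flag the result degenerate.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    if waveforms.ndim != 2:
        raise ValidationError("waveforms must be a 2-D array (events x samples)")
    if n_clusters < 2:
        raise ValueError("need n_clusters >= 2")
    if waveforms.shape[0] < n_clusters:
        raise ValueError(
            f"{waveforms.shape[0]} waveforms cannot form {n_clusters} clusters"
        )
    n_comp = min(n_components, *waveforms.shape)
    coords = PCA(n_components=n_comp, random_state=seed).fit_transform(waveforms)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=n_init)
    labels = km.fit_predict(coords)
    degenerate = len(np.unique(labels)) < 2 or np.allclose(
        waveforms, waveforms[0], atol=1e-12
    )
    sil = None
    if not degenerate:
        sil = float(silhouette_score(coords, labels))
    return WaveformClassification(
        labels=labels, pca_coords=coords, silhouette=sil, degenerate=degenerate
    )
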
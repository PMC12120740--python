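"""Synthetic coupled multimodal slices with known ground truth.

Emulates a recording/sequencing session from one tissue slice: a
high-density microelectrode array (default 64 x 64, 42 µm pitch) with
region-structured LFP event rates, and a lattice of transcriptomic capture
spots (55 µm diameter on ~100 µm centres) whose negative-binomial gene
counts are coupled to the local electrical activity under the spot
footprint.  Spot coordinates are emitted in a frame differing from the
electrode frame by a planted similarity transform, with a homologous
landmark pair given in both frames, so the alignment stage can be tested
against exact ground truth.

Regions are abstract horizontal bands standing in for DG/CA3/CA1/EC — they
exist to exercise region-conditioned statistics, not to model hippocampal
anatomy.  All randomness flows from one integer seed; sub-stages use fixed
offsets from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentTransform, LandmarkSet, invert_transform
from .datatypes import ElectrodeArraySpec, ExpressionMatrix, LFPEventTable

DEFAULT_REGION_RATES = {"DG": 0.8, "CA3": 1.0, "CA1": 0.6, "EC": 0.3}


@dataclass
class SliceParams:
    """Study conditions for one synthetic slice.

    Defaults mirror the real acquisition geometry (64 x 64 electrodes at
    42 µm pitch, 10 min recordings, 55 µm spots) at a desk-scale
    transcriptome of 500 genes and 300 spots.
    """

    rows: int = 64
    cols: int = 64
    pitch: float = 42.0
    electrode_size: float = 21.0
    duration: float = 600.0
    spot_diameter: float = 55.0
    spot_spacing: float = 100.0
    n_spots: int = 300
    n_genes: int = 500
    coupled_frac: float = 0.1
    coupling: float = 0.8
    nb_dispersion: float = 0.5
    region_rates: dict = field(default_factory=lambda: dict(DEFAULT_REGION_RATES))
    rotation_deg: float = 30.0
    scale: float = 1.7
    baseline_log_mean: float = np.log(5.0)
    baseline_log_sd: float = 0.5
    coupled_baseline_shift: float = -1.5
    library_size_sd: float = 0.3
    amplitude_uv: float = 50.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.region_rates.values()):
            raise ValueError("region rates must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.coupled_frac <= 1:
            raise ValueError("coupled_frac must lie in [0, 1]")

    @property
    def array_spec(self) -> ElectrodeArraySpec:
        return ElectrodeArraySpec(
            rows=self.rows,
            cols=self.cols,
            pitch=self.pitch,
            electrode_size=self.electrode_size,
        )


@dataclass
class SliceGroundTruth:
    """Planted quantities behind one synthetic slice."""

    rate_field: np.ndarray
    coupled_genes: list[tuple[str, float]]
    true_rank: int
    true_transform: AlignmentTransform
    region_map: list[str]
    seed: int
    local_rate_per_spot: np.ndarray = None  # type: ignore[assignment]


def _region_bands(y: np.ndarray, y_max: float, names: list[str]) -> list[str]:
    """Assign horizontal bands bottom-to-top over [0, y_max]."""
    edges = np.linspace(0.0, y_max + 1e-9, len(names) + 1)
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(names) - 1)
    return [names[i] for i in idx]


def simulate_multimodal_slice(
    params: SliceParams | None = None,
    seed: int = 0,
) -> tuple[LFPEventTable, ExpressionMatrix, LandmarkSet, SliceGroundTruth]:
    """Draw one coupled slice: events, expression, landmarks, ground truth.

    Events are homogeneous Poisson per electrode at its region's rate.
    Gene counts are negative-binomial with
    ``log-mean = baseline_g + coupling_g * z(local rate)`` where the local
    rate is the mean planted rate of electrodes within the spot footprint
    and ``z`` standardises it across spots.  Spot coordinates are expressed
    in a frame related to the electrode frame by the planted
    rotation/scale; the landmark pairs are exact in both frames.
    """
    params = params or SliceParams()
    spec = params.array_spec
    rng_events = np.random.default_rng(seed)
    rng_spots = np.random.default_rng(seed + 1_000_003)
    rng_expr = np.random.default_rng(seed + 2_000_003)

    # --- electrode rate field and Poisson events -------------------------
    xy = spec.electrode_xy()
    y_max = (spec.rows - 1) * spec.pitch
    region_names = list(params.region_rates)
    elec_regions = _region_bands(xy[:, 1], y_max, region_names)
    rate_field = np.array([params.region_rates[r] for r in elec_regions])

    n_events = rng_events.poisson(rate_field * params.duration)
    rows = []
    for eid in range(spec.n_electrodes):
        k = int(n_events[eid])
        if k == 0:
            continue
        times = np.sort(rng_events.uniform(0.0, params.duration, size=k))
        amps = rng_events.lognormal(np.log(params.amplitude_uv), 0.3, size=k)
        signs = rng_events.choice([-1.0, 1.0], size=k)
        rows.append(
            pd.DataFrame(
                {
                    "electrode_id": str(eid),
                    "time": times,
                    "amplitude": signs * amps,
                    "positive_peaks": 1 + rng_events.poisson(1.0, size=k),
                    "negative_peaks": 1 + rng_events.poisson(1.0, size=k),
                    "energy": amps**2,
                }
            )
        )
    events = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "electrode_id",
                "time",
                "amplitude",
                "positive_peaks",
                "negative_peaks",
                "energy",
            ]
        )
    )
    table = LFPEventTable(events=events, duration=params.duration, array_spec=spec)

    # --- spot lattice over the array extent ------------------------------
    x_max = (spec.cols - 1) * spec.pitch
    gx = np.arange(0.0, x_max + 1e-9, params.spot_spacing)
    gy = np.arange(0.0, y_max + 1e-9, params.spot_spacing)
    lattice = np.array([(x, y) for y in gy for x in gx])
    if params.n_spots < len(lattice):
        pick = np.sort(
            rng_spots.choice(len(lattice), size=params.n_spots, replace=False)
        )
        lattice = lattice[pick]
    spot_regions = _region_bands(lattice[:, 1], y_max, region_names)

    # --- local activity under each spot footprint ------------------------
    r_foot = params.spot_diameter / 2.0 + spec.pitch / 2.0
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    local_rate = np.zeros(len(lattice))
    for s, neighbours in enumerate(tree.query_ball_point(lattice, r=r_foot)):
        if neighbours:
            local_rate[s] = rate_field[neighbours].mean()
    sd = local_rate.std()
    z = (local_rate - local_rate.mean()) / sd if sd > 0 else np.zeros_like(local_rate)

    # --- negative-binomial expression coupled to local activity ----------
    genes = [f"Gene{g:04d}" for g in range(params.n_genes)]
    n_coupled = int(round(params.coupled_frac * params.n_genes))
    coupled_idx = rng_expr.choice(params.n_genes, size=n_coupled, replace=False)
    coeffs = np.zeros(params.n_genes)
    coeffs[coupled_idx] = params.coupling
    baselines = rng_expr.normal(
        params.baseline_log_mean, params.baseline_log_sd, size=params.n_genes
    )
    # activity-coupled genes are IEG-like: induced strongly but a small
    # fraction of total transcript mass, so per-spot totals stay dominated
    # by uncoupled genes and total-count normalization does not imprint
    # the activity signal onto uncoupled genes
    baselines[coupled_idx] += params.coupled_baseline_shift
    library = rng_expr.lognormal(0.0, params.library_size_sd, size=len(lattice))
    mu = np.exp(baselines[:, None] + coeffs[:, None] * z[None, :]) * library[None, :]
    # gamma-poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / params.nb_dispersion
    lam = rng_expr.gamma(shape, mu * params.nb_dispersion)
    counts = rng_expr.poisson(lam).astype(float)

    # --- planted transform and landmarks ---------------------------------
    theta = np.deg2rad(params.rotation_deg)
    k_pt = np.array([x_max / 2.0, y_max / 2.0])
    l_pt = k_pt + 800.0 * np.array([np.cos(0.4), np.sin(0.4)])
    i_pt = np.array([1000.0, 1200.0])
    transform = AlignmentTransform(
        scale=params.scale, theta=float(theta), translation=k_pt, pivot=i_pt
    )
    j_pt = invert_transform(l_pt[None, :], transform)[0]
    spot_xy_srt = invert_transform(lattice, transform)
    landmarks = LandmarkSet(
        i=tuple(i_pt), j=tuple(j_pt), k=tuple(k_pt), l=tuple(l_pt)
    )

    expr = ExpressionMatrix(
        genes=genes,
        spots=[f"SPOT{s:05d}" for s in range(len(lattice))],
        counts=counts,
        spot_xy=spot_xy_srt,
        region=spot_regions,
        normalized=False,
    )
    truth = SliceGroundTruth(
        rate_field=rate_field,
        coupled_genes=[(genes[g], float(coeffs[g])) for g in sorted(coupled_idx)],
        true_rank=4,
        true_transform=transform,
        region_map=spot_regions,
        seed=seed,
        local_rate_per_spot=local_rate,
    )
    return table, expr, landmarks, truth


def default_template(
    fs: float, freq_hz: float = 10.0, cycles: float = 3.0, amplitude: float = 1.0
) -> np.ndarray:
    """Gaussian-windowed sinusoid standing in for an LFP oscillation burst."""
    half = cycles / (2.0 * freq_hz)
    t = np.arange(-half, half, 1.0 / fs)
    # cosine carrier: the waveform extremum sits at the template centre, so
    # a planted event time coincides with the detected extremum
    return amplitude * np.cos(2 * np.pi * freq_hz * t) * np.exp(
        -(t**2) / (2 * (half / 2.5) ** 2)
    )


def simulate_lfp_traces(
    rate_field: np.ndarray,
    waveform_templates: np.ndarray | list[np.ndarray] | None,
    fs: float = 14_000.0,
    duration: float = 10.0,
    seed: int = 0,
    noise_sigma: float = 1.0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """White noise plus template instances at Poisson event times.

    Returns ``(traces, true_times)`` with one trace per entry of
    ``rate_field`` and the planted event times per trace.  A single
    template may be shared, or one given per trace.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 1000:
        raise ValueError("sampling frequency must be >= 1 kHz")
    rate_field = np.atleast_1d(np.asarray(rate_field, dtype=float))
    if np.any(rate_field < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    n_samples = int(round(fs * duration))
    if waveform_templates is None:
        waveform_templates = default_template(fs)
    if isinstance(waveform_templates, np.ndarray) and waveform_templates.ndim == 1:
        templates = [waveform_templates] * rate_field.size
    else:
        templates = list(waveform_templates)
        if len(templates) != rate_field.size:
            raise ValueError("need one template per trace (or a single shared one)")
    traces = rng.normal(0.0, noise_sigma, size=(rate_field.size, n_samples))
    true_times: list[np.ndarray] = []
    for e, rate in enumerate(rate_field):
        k = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=k))
        tpl = np.asarray(templates[e], dtype=float)
        half = tpl.size // 2
        kept = []
        for t in times:
            centre = int(round(t * fs))
            lo, hi = centre - half, centre - half + tpl.size
            if lo < 0 or hi > n_samples:
                continue
            traces[e, lo:hi] += tpl
            kept.append(t)
        true_times.append(np.asarray(kept))
    return traces, true_times


def plant_events(
    trace: np.ndarray, template: np.ndarray, times_s: list[float], fs: float
) -> np.ndarray:
    """Insert a template (centred) at the given times; returns a copy."""
    out = np.asarray(trace, dtype=float).copy()
    tpl = np.asarray(template, dtype=float)
    half = tpl.size // 2
    for t in times_s:
        centre = int(round(t * fs))
        lo, hi = centre - half, centre - half + tpl.size
        if 0 <= lo and hi <= out.size:
            out[lo:hi] += tpl
    return out


def simulate_low_rank_matrix(
    n: int,
    m: int,
    rank: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-negative ``V = W0 @ H0 (+ noise)`` with planted rank.

    Factor entries are sparse-ish gamma draws so the factorisation is
    near-separable; additive Gaussian noise is clipped at zero to keep V
    non-negative.  Used to exercise factorisation-rank selection.
    """
    rng = np.random.default_rng(seed)
    # block-dominant factors: every row/column loads one factor strongly,
    # plus sparse cross-loadings, so the factorisation is near-separable
    w0 = rng.gamma(2.0, 1.0, size=(n, rank)) * (rng.random((n, rank)) < 0.3)
    h0 = rng.gamma(2.0, 1.0, size=(rank, m)) * (rng.random((rank, m)) < 0.3)
    w0[np.arange(n), np.arange(n) % rank] += rng.gamma(4.0, 1.0, size=n)
    h0[np.arange(m) % rank, np.arange(m)] += rng.gamma(4.0, 1.0, size=m)
    v = w0 @ h0
    if noise_sigma > 0:
        v = np.clip(v + rng.normal(0.0, noise_sigma, size=v.shape), 0.0, None)
    return v, w0, h0


def simulate_plane_wave_events(
    spec: ElectrodeArraySpec,
    speed_um_per_s: float,
    onset_s: float = 1.0,
    events_per_electrode: int = 3,
    jitter_s: float = 1e-3,
    duration: float = 10.0,
    seed: int = 0,
) -> LFPEventTable:
    """Events sweeping in +x at a planted speed, for trajectory recovery.

    Each electrode fires ``events_per_electrode`` times around
    ``onset + x / speed`` with Gaussian timing jitter.
    """
    rng = np.random.default_rng(seed)
    xy = spec.electrode_xy()
    rows = []
    for eid in range(spec.n_electrodes):
        t0 = onset_s + xy[eid, 0] / speed_um_per_s
        times = t0 + rng.normal(0.0, jitter_s, size=events_per_electrode)
        times = np.clip(times, 0.0, duration)
        for t in times:
            rows.append(
                {
                    "electrode_id": str(eid),
                    "time": float(t),
                    "amplitude": 50.0,
                    "positive_peaks": 1,
                    "negative_peaks": 1,
                    "energy": 2500.0,
                }
            )
    return LFPEventTable(
        events=pd.DataFrame(rows), duration=duration, array_spec=spec
    )
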
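"""Trace physiology: evoked-response latency, event frequency, and kinetics.

Latency is measured from the beginning of the stimulation artifact (first
suprathreshold |dV/dt| sample after the stimulus marker) to the beginning of
the EPSP (muscle depolarization). The EPSP onset is located by a threshold
crossing (baseline mean + k.SD sustained for m samples, after blanking the
artifact) and refined to near-sample precision with a hinge (baseline +
linear-rise) least-squares fit around the crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks


@dataclass
class Trace:
    """Uniformly sampled voltage trace with stimulus markers."""

    voltage_mv: np.ndarray
    sampling_rate_hz: float
    stim_times_ms: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.voltage_mv.ndim != 1:
            raise ValueError("voltage must be 1D")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def duration_ms(self) -> float:
        return (len(self.voltage_mv) - 1) * self.sample_period_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.voltage_mv)) * self.sample_period_ms

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, stim_times_ms: list[float] | None = None
    ) -> "Trace":
        t = frame["time_ms"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("trace is not uniformly sampled")
        fs = 1000.0 / dt[0] if len(dt) else 1.0
        return cls(
            voltage_mv=frame["voltage_mv"].to_numpy(dtype=float),
            sampling_rate_hz=fs,
            stim_times_ms=list(stim_times_ms or []),
        )


@dataclass
class LatencyResult:
    """Per-stimulus latencies with response/failure bookkeeping."""

    per_stimulus: pd.DataFrame  # stim_time_ms, artifact_onset_ms,
    #                             epsp_onset_ms, latency_ms, responded
    mean_latency_ms: float
    sd_latency_ms: float
    response_probability: float


def _backextrapolate_onset(
    v: np.ndarray,
    crossing: int,
    height: float,
    baseline_mean: float,
    lo_bound: int,
    hi_bound: int,
    lo_frac: float = 0.25,
    hi_frac: float = 0.8,
) -> float:
    """Locate a depolarization onset by rising-phase back-extrapolation.

    Starting from the threshold crossing (a point on the rising phase), the
    ascending limb is delimited by walking back to the ``lo_frac``-height
    level and forward to the ``hi_frac``-height level (``height`` is a
    robust estimate of the response amplitude over baseline). A straight
    line fit to that limb is extrapolated down to the baseline mean — the
    manual-cursor convention for EPSP onset, unbiased for a linearly rising
    front. Falls back to the limb's lowest sample when a fit is impossible.
    """
    if height <= 0:
        return float(crossing)
    lo_level = baseline_mean + lo_frac * height
    hi_level = baseline_mean + hi_frac * height
    j_lo = min(crossing, hi_bound - 1)
    while j_lo - 1 >= lo_bound and v[j_lo - 1] >= lo_level:
        j_lo -= 1
    j_hi = j_lo
    while j_hi + 1 < hi_bound and v[j_hi] < hi_level:
        j_hi += 1
    rise = list(range(j_lo, j_hi + 1))
    if len(rise) < 2:
        return float(j_lo)
    x = np.asarray(rise, dtype=float)
    y = v[rise]
    b, a = np.polyfit(x, y, 1)
    if b <= 0:
        return float(j_lo)
    onset = (baseline_mean - a) / b
    return float(np.clip(onset, lo_bound, hi_bound))


def detect_latency(
    trace: Trace,
    k_sd: float = 3.0,
    persistence_samples: int = 5,
    baseline_window_ms: float | None = None,
    artifact_window_ms: float = 1.0,
    artifact_blank_ms: float = 0.3,
    response_window_ms: float = 20.0,
    artifact_slope_factor: float = 10.0,
    refine_window_samples: int = 40,
    smooth_samples: int = 7,
) -> LatencyResult:
    """Measure per-stimulus response latency on an intracellular trace.

    For each stimulus marker: the artifact onset is the first sample within
    ``artifact_window_ms`` whose |dV/dt| exceeds ``artifact_slope_factor``
    times the baseline derivative spread (always > 0); after blanking
    ``artifact_blank_ms``, the EPSP onset is the first sample exceeding
    baseline mean + ``k_sd``.SD for ``persistence_samples`` consecutive
    samples, refined by a hinge fit. A stimulus with no qualifying crossing
    inside ``response_window_ms`` is flagged as a failure (not an error);
    a missing artifact is an error. The mean latency is computed over
    responses only.
    """
    if not trace.stim_times_ms:
        raise ValueError("trace carries no stimulus markers")
    v = trace.voltage_mv
    dt_ms = trace.sample_period_ms
    first_stim_idx = int(round(min(trace.stim_times_ms) / dt_ms))
    if baseline_window_ms is None:
        base_lo = 0
    else:
        base_lo = max(first_stim_idx - int(round(baseline_window_ms / dt_ms)), 0)
    if first_stim_idx - base_lo < 2:
        raise ValueError("baseline window must precede the first stimulus")
    baseline = v[base_lo:first_stim_idx]
    base_mean = float(baseline.mean())
    base_sd = float(baseline.std())
    dv = np.abs(np.diff(v))
    base_dv_sd = float(np.abs(np.diff(baseline)).std())
    slope_thr = artifact_slope_factor * max(base_dv_sd, 1e-9)

    # symmetric smoothing preserves the back-extrapolated corner of a linear
    # rise exactly while suppressing sample-to-sample noise
    k = max(int(smooth_samples) | 1, 1)
    if k > 1 and base_sd > 0:
        kernel = np.ones(k) / k
        v_smooth = np.convolve(v, kernel, mode="same")
    else:
        v_smooth = v

    rows = []
    for stim_ms in trace.stim_times_ms:
        stim_idx = int(round(stim_ms / dt_ms))
        art_hi = min(stim_idx + int(round(artifact_window_ms / dt_ms)), len(dv))
        art_region = dv[stim_idx:art_hi]
        above = np.nonzero(art_region > slope_thr)[0]
        if above.size == 0:
            raise ValueError(f"no stimulation artifact found after t={stim_ms} ms")
        art_idx = stim_idx + int(above[0])

        search_lo = art_idx + int(round(artifact_blank_ms / dt_ms))
        search_hi = min(
            stim_idx + int(round(response_window_ms / dt_ms)), len(v)
        )
        thr = base_mean + k_sd * base_sd
        onset_idx = None
        seg = v[search_lo:search_hi]
        above = seg > thr
        m = max(persistence_samples, 1)
        if above.size >= m:
            sustained = np.convolve(above.astype(int), np.ones(m, dtype=int), "valid") == m
            hits = np.nonzero(sustained)[0]
            if hits.size:
                crossing = search_lo + int(hits[0])
                # a high quantile of the post-crossing window is a height
                # reference immune to isolated noise bumps on the decay
                win_hi = min(search_hi, crossing + refine_window_samples)
                height = float(
                    np.quantile(v_smooth[crossing:win_hi], 0.9) - base_mean
                )
                onset_idx = _backextrapolate_onset(
                    v_smooth,
                    crossing,
                    height,
                    base_mean,
                    lo_bound=search_lo,
                    hi_bound=win_hi,
                )
        responded = onset_idx is not None
        latency = (onset_idx - art_idx) * dt_ms if responded else np.nan
        rows.append(
            {
                "stim_time_ms": stim_ms,
                "artifact_onset_ms": art_idx * dt_ms,
                "epsp_onset_ms": onset_idx * dt_ms if responded else np.nan,
                "latency_ms": latency,
                "responded": responded,
            }
        )
    per_stim = pd.DataFrame(rows)
    responses = per_stim.loc[per_stim["responded"], "latency_ms"]
    return LatencyResult(
        per_stimulus=per_stim,
        mean_latency_ms=float(responses.mean()) if len(responses) else float("nan"),
        sd_latency_ms=float(responses.std(ddof=0)) if len(responses) else float("nan"),
        response_probability=float(per_stim["responded"].mean()),
    )


def response_frequency(
    trace: Trace,
    window_s: float = 5.0,
    start_ms: float = 0.0,
    k_sd: float = 5.0,
    threshold_mv: float | None = None,
    min_separation_ms: float = 5.0,
) -> float:
    """Suprathreshold event rate (Hz) within a window of the trace.

    Events are peaks above baseline mean + ``k_sd``.SD (relative criterion;
    ``threshold_mv`` overrides with an absolute level), separated by at least
    ``min_separation_ms``. The window must lie within the trace.
    """
    dt_ms = trace.sample_period_ms
    lo = int(round(start_ms / dt_ms))
    hi = int(round((start_ms + window_s * 1000.0) / dt_ms))
    if lo < 0 or hi > len(trace.voltage_mv):
        raise ValueError("analysis window exceeds the trace extent")
    seg = trace.voltage_mv[lo:hi]
    if threshold_mv is None:
        med = float(np.median(seg))
        mad = float(np.median(np.abs(seg - med)))
        thr = med + k_sd * max(mad * 1.4826, 1e-9)
    else:
        thr = threshold_mv
    peaks, _ = find_peaks(
        seg, height=thr, distance=max(int(round(min_separation_ms / dt_ms)), 1)
    )
    return len(peaks) / window_s


def proteasome_slope(series: pd.DataFrame, t_min: float | None = None, t_max: float | None = None):
    """OLS slope of fluorogenic-product accumulation over time.

    ``series`` has columns ``time_min`` and ``fluorescence``; an optional
    sub-range restricts the fit. Returns an object with ``slope`` (a.u./min),
    ``intercept``, and ``r_squared``. Fewer than 3 points is an error.
    """
    t = series["time_min"].to_numpy(dtype=float)
    y = series["fluorescence"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time values must be strictly increasing")
    keep = np.ones(t.size, dtype=bool)
    if t_min is not None:
        keep &= t >= t_min
    if t_max is not None:
        keep &= t <= t_max
    t, y = t[keep], y[keep]
    if t.size < 3:
        raise ValueError("need at least 3 points for a kinetic slope")
    fit = stats.linregress(t, y)
    return SlopeResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0,
        n_points=int(t.size),
    )


@dataclass
class SlopeResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
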
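"""Awake-hemodynamics analysis: locomotion events, HRF deconvolution and
gamma-variate response modeling.

The processing chain treats neurovascular coupling as a linear time-invariant
system.  Treadmill velocity is low-pass filtered and binarized by an
acceleration threshold into locomotion events; the hemodynamic response
function (HRF) is recovered by least-squares deconvolution of the measured
signal against the binarized event train (Toeplitz design with an intercept
column); and the kernel is summarized by fitting a gamma-variate

    HRF(t; A, T, W) = A (t/T)^alpha exp(-(t-T)/beta),
    alpha = (T/W)^2 8 ln 2,   beta = W^2 / (T 8 ln 2),

which peaks at value A at time T with half-maximum width ~W.  Response
metrics (amplitude, time to peak, FWHM) are read off the fitted kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import minimize
from scipy.stats import linregress

from .synthetic import BehaviorTrace, events_to_delta, gamma_variate  # noqa: F401

LN2_8 = 8.0 * np.log(2.0)


@dataclass
class LocomotionEvents:
    """Binarized locomotion detection and its merged event intervals."""

    delta: np.ndarray  # binary vector, one entry per sample
    fs_hz: float
    a_c: float = 3.0
    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if not np.all(np.isin(self.delta, (0.0, 1.0))):
            raise ValueError("delta must be binary")
        for (a0, b0), (a1, b1) in zip(self.events, self.events[1:]):
            if a1 < b0:
                raise ValueError("events must be ordered and non-overlapping")

    @property
    def duration_s(self) -> float:
        return self.delta.size / self.fs_hz

    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.events])


def detect_locomotion(
    trace: BehaviorTrace,
    lp_cutoff_hz: float = 10.0,
    lp_order: int = 5,
    a_c: float = 3.0,
    merge_gap_s: float = 0.5,
) -> LocomotionEvents:
    """Detect locomotion bouts from a treadmill velocity trace.

    Velocity is zero-phase low-pass filtered (Butterworth, default 10 Hz,
    5th order), differentiated by central differences to acceleration, and
    binarized at ``|a| >= a_c`` (default 3 cm/s²).  Runs of 1s separated by
    gaps shorter than ``merge_gap_s`` are merged into events — treadmill
    acceleration crosses zero within a running bout (e.g. at each stride), so
    unmerged threshold crossings would fragment bouts.
    """
    fs = trace.fs_hz
    if fs <= 2 * lp_cutoff_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {lp_cutoff_hz} Hz low-pass"
        )
    sos = sps.butter(lp_order, lp_cutoff_hz, btype="low", fs=fs, output="sos")
    v = sps.sosfiltfilt(sos, trace.velocity_cmps)
    a = np.gradient(v) * fs  # central differences, cm/s²
    delta = (np.abs(a) >= a_c).astype(float)

    events = _runs_to_events(delta, fs, merge_gap_s)
    merged = np.zeros_like(delta)
    for onset, offset in events:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        merged[i0:i1] = 1.0
    return LocomotionEvents(delta=merged, fs_hz=fs, a_c=a_c, events=events)


def _runs_to_events(delta: np.ndarray, fs: float, merge_gap_s: float):
    idx = np.flatnonzero(delta > 0)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1  # half-open
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if (s - merged[-1][1]) / fs < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s / fs, e / fs) for s, e in merged]


def resting_periods(
    events: LocomotionEvents | list[tuple[float, float]],
    duration_s: float,
    post_gap_s: float = 4.0,
    min_len_s: float = 60.0,
) -> list[tuple[float, float]]:
    """Resting intervals: from 4 s after each locomotion offset to the next
    onset, kept only if at least 60 s long.

    The session start is treated as an event offset at t=0 (so a session with
    no events yields the whole trace minus the leading 4 s, if long enough),
    and the session end closes the final candidate.
    """
    intervals = events.events if isinstance(events, LocomotionEvents) else list(events)
    bounds = [(None, 0.0)] + sorted(intervals) + [(duration_s, None)]
    rests = []
    for (_, prev_end), (next_start, _) in zip(bounds, bounds[1:]):
        start = prev_end + post_gap_s
        if next_start - start >= min_len_s:
            rests.append((start, next_start))
    return rests


@dataclass
class TriggeredAverage:
    time_s: np.ndarray  # relative to the alignment point
    mean: np.ndarray
    sem: np.ndarray
    n_events: int


def triggered_average(
    signal: np.ndarray,
    fs_hz: float,
    events: LocomotionEvents | list[tuple[float, float]],
    min_event_s: float = 5.0,
    pre_s: float = 2.0,
    post_s: float = 10.0,
    align: str = "onset",
) -> TriggeredAverage:
    """Event-triggered average of a signal, mean ± SEM across events.

    Only events at least ``min_event_s`` long (default 5 s) whose full
    ``[-pre_s, post_s]`` window lies inside the trace are used; ``align``
    selects onset- or offset-locked averaging.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    signal = np.asarray(signal, dtype=float)
    intervals = events.events if isinstance(events, LocomotionEvents) else list(events)
    pre_n, post_n = int(round(pre_s * fs_hz)), int(round(post_s * fs_hz))
    windows = []
    for onset, offset in intervals:
        if offset - onset < min_event_s:
            continue
        t0 = onset if align == "onset" else offset
        i = int(round(t0 * fs_hz))
        if i - pre_n < 0 or i + post_n > signal.size:
            continue
        windows.append(signal[i - pre_n : i + post_n])
    if not windows:
        raise ValueError(
            f"no qualifying events (>= {min_event_s} s with a full window in the trace)"
        )
    stack = np.vstack(windows)
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        if stack.shape[0] > 1
        else np.zeros_like(mean)
    )
    t = (np.arange(-pre_n, post_n)) / fs_hz
    return TriggeredAverage(t, mean, sem, stack.shape[0])


# ---------------------------------------------------------------------------
# HRF deconvolution and gamma-variate modeling
# ---------------------------------------------------------------------------


@dataclass
class HRFModel:
    """Deconvolved HRF kernel and (optionally) its gamma-variate fit.

    ``kernel[0]`` is the intercept (signal offset); ``kernel[1:]`` is the
    response at lags ``1/fs .. k/fs``.  ``alpha`` and ``beta`` are derived
    exactly from the stored (T, W), so ``alpha * beta == T`` algebraically.
    """

    kernel: np.ndarray
    fs_hz: float
    A: float | None = None
    T: float | None = None
    W: float | None = None
    r2: float | None = None
    model_kernel: np.ndarray | None = None
    amplitude: float | None = None
    ttp_s: float | None = None
    fwhm_s: float | None = None

    @property
    def offset(self) -> float:
        return float(self.kernel[0])

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(1, self.kernel.size) / self.fs_hz

    @property
    def alpha(self) -> float:
        return (self.T / self.W) ** 2 * LN2_8

    @property
    def beta(self) -> float:
        return self.W**2 / (self.T * LN2_8)


def build_design_matrix(delta: np.ndarray, k_lags: int) -> np.ndarray:
    """Toeplitz design: leading all-ones intercept column, then the event
    vector shifted down by 1..k lags."""
    m = delta.size
    L = np.zeros((m, k_lags + 1))
    L[:, 0] = 1.0
    for j in range(1, k_lags + 1):
        L[j:, j] = delta[: m - j]
    return L


def deconvolve_hrf(
    signal: np.ndarray,
    events: LocomotionEvents | np.ndarray,
    fs_hz: float | None = None,
    k_seconds: float = 10.0,
    k_lags: int | None = None,
) -> HRFModel:
    """Least-squares deconvolution of a signal against binarized events.

    Solves ``min ||L H - V||₂`` via the pseudo-inverse (identical to the
    normal-equation solution when L has full column rank, and defined when it
    does not).  ``H[0]`` absorbs the signal offset; ``H[1:]`` is the kernel.
    The default kernel span of 10 s covers locomotion-evoked responses.
    """
    if isinstance(events, LocomotionEvents):
        delta, fs = events.delta, events.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required with a raw delta vector")
        delta, fs = np.asarray(events, dtype=float), float(fs_hz)
    V = np.asarray(signal, dtype=float)
    if V.shape != delta.shape:
        raise ValueError("signal and event vector must have the same length")
    if not np.any(delta):
        raise ValueError("event vector is all zeros; the HRF is unidentifiable")
    k = int(k_lags) if k_lags is not None else int(round(k_seconds * fs))
    if k < 1:
        raise ValueError("need at least one lag")
    if k >= V.size:
        raise ValueError(f"kernel length {k} must be shorter than the signal ({V.size})")
    L = build_design_matrix(delta, k)
    H, *_ = np.linalg.lstsq(L, V, rcond=None)
    return HRFModel(kernel=H, fs_hz=fs)


def _gamma_sse(params, t, y):
    logT, logW, A = params
    model = gamma_variate(t, A, np.exp(logT), np.exp(logW))
    return float(np.sum((y - model) ** 2))


def fit_gamma_variate(
    kernel: np.ndarray | HRFModel,
    fs_hz: float | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> HRFModel:
    """Fit (A, T, W) to a deconvolved kernel by downhill simplex.

    Nelder-Mead minimizes the sum of squared differences between the kernel
    samples (lags 1/fs..k/fs) and the gamma-variate model.  T and W are
    optimized in log space to stay positive.  The simplex starts from
    moment-based guesses (peak value, peak time, half-maximum width) plus
    jittered restarts with a fixed seed; goodness of fit is

        R² = 1 − Σ(actual − model)² / Σ(actual − mean(actual))².
    """
    if isinstance(kernel, HRFModel):
        model_in, fs = kernel, kernel.fs_hz
        y = kernel.kernel[1:]
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required with a raw kernel vector")
        fs = float(fs_hz)
        y = np.asarray(kernel, dtype=float)
        model_in = HRFModel(kernel=np.concatenate([[0.0], y]), fs_hz=fs)
    if y.size < 4:
        raise ValueError("kernel must have at least 4 lag samples")
    if np.allclose(y, y[0]):
        raise ValueError("kernel is constant; gamma-variate fit undefined")
    t = np.arange(1, y.size + 1) / fs

    i_peak = int(np.argmax(np.abs(y)))
    A0 = float(y[i_peak])
    T0 = max(t[i_peak], 2.0 / fs)
    above = np.abs(y) >= 0.5 * np.abs(A0)
    W0 = max(above.sum() / fs, 2.0 / fs)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        jitter = np.ones(3) if r == 0 else rng.uniform(0.7, 1.3, size=3)
        x0 = np.array([np.log(T0 * jitter[0]), np.log(W0 * jitter[1]), A0 * jitter[2]])
        res = minimize(
            _gamma_sse,
            x0,
            args=(t, y),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("gamma-variate fit failed to converge")

    T, W, A = float(np.exp(best.x[0])), float(np.exp(best.x[1])), float(best.x[2])
    fitted = gamma_variate(t, A, T, W)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    out = HRFModel(
        kernel=model_in.kernel,
        fs_hz=fs,
        A=A,
        T=T,
        W=W,
        r2=r2,
        model_kernel=np.concatenate([[model_in.kernel[0]], fitted]),
    )
    out.amplitude, out.ttp_s, out.fwhm_s = hrf_metrics(out)
    return out


def hrf_metrics(model: HRFModel, grid_dt_s: float = 1e-3) -> tuple[float, float, float]:
    """(amplitude, time to peak, FWHM) of the fitted gamma-variate kernel.

    Evaluated on a fine time grid; the half-maximum crossings are located by
    linear interpolation.  The amplitude is the modeled peak value and TTP the
    time at which the model attains it.
    """
    if model.T is None:
        raise ValueError("model has no fitted gamma-variate parameters")
    t_end = model.T + 20.0 * model.beta  # well past the decay
    t = np.arange(0.0, t_end, grid_dt_s)
    y = gamma_variate(t, model.A, model.T, model.W)
    i = int(np.argmax(y))
    amplitude = float(y[i])
    ttp = float(t[i])
    half = 0.5 * amplitude
    above = y >= half
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]

    def cross(j0, j1):
        if j0 < 0 or j1 >= y.size or y[j1] == y[j0]:
            return t[max(j0, 0)]
        return t[j0] + (half - y[j0]) / (y[j1] - y[j0]) * (t[j1] - t[j0])

    t_rise = cross(i0 - 1, i0)
    t_fall = cross(i1, i1 + 1)
    return amplitude, ttp, float(t_fall - t_rise)


def hbt_oxy_regression(
    hbt: np.ndarray,
    oxy_index: np.ndarray,
    events: LocomotionEvents | list[tuple[float, float]],
    fs_hz: float,
    window_s: tuple[float, float] = (2.0, 5.0),
) -> tuple[float, float, float]:
    """OLS regression of per-event oxygenation response on ΔHbT response.

    For every locomotion event, ΔHbT and ΔHbO−ΔHbR are averaged over the
    window (default 2-5 s) after onset; the pairs are fit with an ordinary
    least squares line.  Returns (slope, intercept, r).
    """
    hbt = np.asarray(hbt, dtype=float)
    oxy_index = np.asarray(oxy_index, dtype=float)
    intervals = events.events if isinstance(events, LocomotionEvents) else list(events)
    xs, ys = [], []
    for onset, _ in intervals:
        i0 = int(round((onset + window_s[0]) * fs_hz))
        i1 = int(round((onset + window_s[1]) * fs_hz))
        if i0 < 0 or i1 > hbt.size or i1 <= i0:
            continue
        xs.append(hbt[i0:i1].mean())
        ys.append(oxy_index[i0:i1].mean())
    if len(xs) < 2:
        raise ValueError("need at least two events with full windows for a regression")
    res = linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue)
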
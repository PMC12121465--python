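"""Metrics for circadian bioluminescence / fluorescence recordings.

A recording is a uniformly sampled signal from a tissue explant expressing a
luminescent or fluorescent circadian reporter.  Recordings are split into
named epochs (``baseline`` / ``treatment`` / ``washout``) around a
pharmacological manipulation, and the quantities of interest are the
oscillation's period, cycle amplitudes normalized to the last pre-treatment
cycle, the phase shift produced by the treatment, the rising/falling
amplitude asymmetry during recovery (B/A ratio), the relative amplitude
error (RAE) of a damped-cosine fit, and circular statistics of peak phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats


class FitDivergenceWarning(UserWarning):
    """Raised (as a warning) when the oscillator fit fails to converge."""


@dataclass
class Trace:
    """A single reporter recording.

    Parameters
    ----------
    time_h : array of hours, strictly increasing, uniformly spaced.
    value : signal in arbitrary units; NaN marks excluded samples.
    epochs : optional mapping of epoch name -> (start_h, end_h).
    reporter : free-text reporter label (e.g. ``"Per2::Luc"``).
    truth : ground-truth annotations when the trace was simulated.
    """

    time_h: np.ndarray
    value: np.ndarray
    epochs: dict = field(default_factory=dict)
    reporter: str = ""
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.value.shape:
            raise ValueError("time_h and value must be 1-D arrays of equal length")
        if self.time_h.size < 2:
            raise ValueError("a trace needs at least two samples")
        steps = np.diff(self.time_h)
        if np.any(steps <= 0):
            raise ValueError("time_h must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform within a recording")
        _check_epochs(self.epochs)

    @property
    def dt_h(self) -> float:
        return float(self.time_h[1] - self.time_h[0])

    def copy(self, **changes) -> "Trace":
        out = replace(self, **changes)
        out.value = np.array(out.value, dtype=float, copy=True)
        out.time_h = np.array(out.time_h, dtype=float, copy=True)
        return out

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.time_h, "value": self.value}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, epochs: Mapping | None = None, reporter: str = "") -> "Trace":
        df = pd.read_csv(path)
        return cls(
            time_h=df["time_h"].to_numpy(),
            value=df["value"].to_numpy(),
            epochs=dict(epochs or {}),
            reporter=reporter,
        )


def _check_epochs(epochs: Mapping) -> None:
    spans = sorted((float(a), float(b)) for a, b in epochs.values())
    for (a, b) in spans:
        if a >= b:
            raise ValueError(f"epoch start {a} must precede end {b}")
    for (_, b0), (a1, _) in zip(spans, spans[1:]):
        if a1 < b0 - 1e-9:
            raise ValueError("epochs must be non-overlapping")


@dataclass
class PeakSet:
    """Alternating local maxima and minima of a recording."""

    peak_times_h: np.ndarray
    peak_values: np.ndarray
    trough_times_h: np.ndarray
    trough_values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("peak_times_h", "peak_values", "trough_times_h", "trough_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        events = sorted(
            [(t, "p") for t in self.peak_times_h] + [(t, "t") for t in self.trough_times_h]
        )
        for (_, k0), (_, k1) in zip(events, events[1:]):
            if k0 == k1:
                raise ValueError("peaks and troughs must strictly alternate in time")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times_h.size)


@dataclass
class NllsFit:
    """A linear-detrended single-cosine fit ``c0 + c1*t + A*cos(2pi(t-phi)/tau)``."""

    offset: float
    slope: float
    amplitude: float
    period_h: float
    phase_h: float
    amplitude_se: float
    n_obs: int = 0
    converged: bool = True


@dataclass
class CycleMetrics:
    """Per-trace summary of the rhythm analytics."""

    period_baseline_h: float = np.nan
    period_treatment_h: float = np.nan
    delta_period_h: float = np.nan
    normalized_amplitudes: pd.DataFrame | None = None
    phase_shift_h: float = np.nan
    ba_ratios: pd.DataFrame | None = None
    steady_state_ba: float = np.nan
    rae_baseline: float = np.nan
    rae_treatment: float = np.nan
    rae_normalized: float = np.nan


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def detrend(trace: Trace, baseline_fit_window_h: float = 72.0) -> Trace:
    """Subtract a line fitted to the end of the baseline epoch.

    The line is fitted by least squares to the last ``baseline_fit_window_h``
    hours of the baseline epoch and subtracted from the trace from the start
    of the fit window onward (i.e. it is projected forward through treatment
    and washout); earlier samples are left untouched.
    """
    if "baseline" not in trace.epochs:
        raise ValueError("trace has no 'baseline' epoch to detrend against")
    b0, b1 = trace.epochs["baseline"]
    if b1 - b0 < baseline_fit_window_h - 1e-9:
        raise ValueError(
            f"baseline epoch ({b1 - b0:.1f} h) shorter than fit window "
            f"({baseline_fit_window_h:.1f} h)"
        )
    w0 = b1 - baseline_fit_window_h
    t, v = trace.time_h, trace.value
    in_window = (t >= w0 - 1e-9) & (t <= b1 + 1e-9)
    ok = in_window & np.isfinite(v)
    slope, intercept = np.polyfit(t[ok], v[ok], 1)
    out = trace.copy()
    after = t >= w0 - 1e-9
    out.value[after] = v[after] - (slope * t[after] + intercept)
    return out


def smooth(trace: Trace, window_points: int = 5) -> Trace:
    """Centered moving average; window shrinks symmetrically at the ends."""
    if window_points < 1 or window_points % 2 == 0:
        raise ValueError("window_points must be odd and >= 1")
    n = trace.value.size
    if window_points > n:
        raise ValueError("smoothing window longer than the trace")
    half = window_points // 2
    v = trace.value
    out_v = np.empty_like(v)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out_v[i] = np.nanmean(v[lo:hi])
    out = trace.copy()
    out.value = out_v
    return out


# ---------------------------------------------------------------------------
# peak detection and peak-based metrics
# ---------------------------------------------------------------------------

def _refine_extremum(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid extremum location by a parabola through three samples."""
    if i == 0 or i == v.size - 1:
        return float(t[i]), float(v[i])
    denom = v[i - 1] - 2 * v[i] + v[i + 1]
    if denom == 0 or not np.isfinite(denom):
        return float(t[i]), float(v[i])
    delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[1] - t[0]
    return float(t[i] + delta * dt), float(v[i] - 0.25 * (v[i - 1] - v[i + 1]) * delta)


def find_peaks_troughs(
    trace: Trace,
    min_separation_h: float = 16.0,
    min_prominence_frac: float = 0.2,
    refine: bool = True,
) -> PeakSet:
    """Detect alternating peaks and troughs of a circadian recording.

    Local extrema must be separated by ``min_separation_h`` hours and have a
    prominence of at least ``min_prominence_frac`` times the interquartile
    range of the signal.  When two same-kind extrema remain adjacent the
    lesser (lower peak / higher trough) is dropped so the result alternates.
    """
    t, v = trace.time_h, trace.value
    finite = np.isfinite(v)
    iqr = float(np.subtract(*np.percentile(v[finite], [75, 25])))
    prom = min_prominence_frac * iqr if iqr > 0 else None
    distance = max(1, int(round(min_separation_h / trace.dt_h)))
    vv = np.where(finite, v, np.nanmedian(v))
    p_idx, _ = signal.find_peaks(vv, distance=distance, prominence=prom)
    q_idx, _ = signal.find_peaks(-vv, distance=distance, prominence=prom)

    events = [(i, +1) for i in p_idx] + [(i, -1) for i in q_idx]
    events.sort()
    # enforce alternation: among same-kind neighbours keep the more extreme
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            j, _ = kept[-1]
            better = (kind == +1 and vv[i] > vv[j]) or (kind == -1 and vv[i] < vv[j])
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))

    def _collect(kind: int) -> tuple[np.ndarray, np.ndarray]:
        ts, vs = [], []
        for i, k in kept:
            if k != kind:
                continue
            if refine:
                ti, vi = _refine_extremum(t, vv, i)
            else:
                ti, vi = float(t[i]), float(vv[i])
            ts.append(ti)
            vs.append(vi)
        return np.asarray(ts), np.asarray(vs)

    pk_t, pk_v = _collect(+1)
    tr_t, tr_v = _collect(-1)
    if pk_t.size == 0:
        warnings.warn("no qualifying peak found", UserWarning, stacklevel=2)
    return PeakSet(pk_t, pk_v, tr_t, tr_v)


def compute_period(peaks: PeakSet, interval: tuple[float, float] | None = None) -> float:
    """Mean peak-to-peak spacing of peaks inside ``interval`` (hours)."""
    times = peaks.peak_times_h
    if interval is not None:
        a, b = interval
        times = times[(times >= a) & (times <= b)]
    if times.size < 2:
        warnings.warn("fewer than two peaks in interval; period undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    return float(np.mean(np.diff(np.sort(times))))


def delta_period(baseline_period_h: float, treatment_period_h: float) -> float:
    """Treatment-minus-baseline change in mean period (hours)."""
    return float(treatment_period_h - baseline_period_h)


def _cycles(peaks: PeakSet) -> pd.DataFrame:
    """One row per peak with its flanking troughs (NaN when missing)."""
    rows = []
    tr_t, tr_v = peaks.trough_times_h, peaks.trough_values
    for pt, pv in zip(peaks.peak_times_h, peaks.peak_values):
        before = tr_t < pt
        after = tr_t > pt
        rows.append(
            {
                "peak_time_h": pt,
                "peak_value": pv,
                "pre_trough_time_h": tr_t[before][-1] if before.any() else np.nan,
                "pre_trough_value": tr_v[before][-1] if before.any() else np.nan,
                "post_trough_time_h": tr_t[after][0] if after.any() else np.nan,
                "post_trough_value": tr_v[after][0] if after.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cycle_amplitudes(peaks: PeakSet, treatment_start_h: float) -> pd.DataFrame:
    """Trough-to-peak amplitudes normalized to the last pre-treatment cycle."""
    cyc = _cycles(peaks)
    cyc["amplitude"] = np.abs(cyc["peak_value"] - cyc["pre_trough_value"])
    ref = cyc[(cyc["peak_time_h"] < treatment_start_h) & cyc["amplitude"].notna()]
    if ref.empty:
        raise ValueError("no complete pre-treatment reference cycle (missing trough?)")
    ref_amp = float(ref["amplitude"].iloc[-1])
    cyc["normalized_amplitude"] = cyc["amplitude"] / ref_amp
    return cyc[["peak_time_h", "amplitude", "normalized_amplitude"]]


def phase_shift(
    peaks: PeakSet, baseline_period_h: float, treatment_start_h: float
) -> float:
    """Phase shift (hours) of the second post-treatment peak.

    The expected peak time is extrapolated from the last pre-treatment peak
    by two baseline periods; the shift is predicted minus observed, so an
    advance (peak earlier than expected) is positive and a delay negative.
    """
    pre = peaks.peak_times_h[peaks.peak_times_h < treatment_start_h]
    post = peaks.peak_times_h[peaks.peak_times_h >= treatment_start_h]
    if pre.size < 1 or post.size < 2:
        warnings.warn("insufficient peaks to estimate the phase shift", UserWarning,
                      stacklevel=2)
        return float("nan")
    predicted = pre[-1] + 2.0 * baseline_period_h
    observed = post[1]
    return float(predicted - observed)


def ba_ratio(peaks: PeakSet) -> pd.DataFrame:
    """Rising/falling amplitude ratio per cycle.

    B is the amplitude from the preceding trough to the peak, A the amplitude
    from the peak to the following trough.  A stationary oscillation has
    B/A = 1; a growing oscillation (recovery after washout) has B/A < 1.
    Peaks missing a flanking trough are skipped.
    """
    cyc = _cycles(peaks)
    b = cyc["peak_value"] - cyc["pre_trough_value"]
    a = cyc["peak_value"] - cyc["post_trough_value"]
    out = pd.DataFrame(
        {"peak_time_h": cyc["peak_time_h"], "b": b, "a": a, "ba_ratio": b / a}
    )
    return out.dropna().reset_index(drop=True)


def steady_state_ba(peaks: PeakSet, washout_start_h: float) -> float:
    """B/A ratio at the second post-washout peak (the steady-state value)."""
    ratios = ba_ratio(peaks)
    post = ratios[ratios["peak_time_h"] >= washout_start_h]
    if len(post) < 2:
        warnings.warn("fewer than two complete post-washout cycles", UserWarning,
                      stacklevel=2)
        return float("nan")
    return float(post["ba_ratio"].iloc[1])


# ---------------------------------------------------------------------------
# cosine fitting and RAE
# ---------------------------------------------------------------------------

def fit_fft_nlls(
    trace: Trace,
    period_window_h: tuple[float, float] = (18.0, 30.0),
    interval: tuple[float, float] | None = None,
) -> NllsFit:
    """Nonlinear least-squares fit of a linear-detrended cosine.

    The model is ``offset + slope*t + A*cos(2pi(t - phi)/tau)``.  Initial
    period, amplitude and phase come from the dominant discrete-Fourier
    component whose period falls inside ``period_window_h``; the fit then
    refines all five parameters.  The amplitude standard error is taken from
    the curvature-based covariance of the fit.
    """
    t, v = trace.time_h, trace.value
    if interval is not None:
        m = (t >= interval[0]) & (t <= interval[1])
        t, v = t[m], v[m]
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    lo, hi = period_window_h
    if t[-1] - t[0] < 2 * lo:
        raise ValueError("need at least two cycles of data to fit")

    slope0, off0 = np.polyfit(t, v, 1)
    resid = v - (off0 + slope0 * t)
    dt = float(np.median(np.diff(t)))
    spec = np.fft.rfft(resid)
    freqs = np.fft.rfftfreq(resid.size, d=dt)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-12), np.inf)
    in_win = (periods >= lo) & (periods <= hi)
    if not in_win.any():
        in_win = freqs > 0  # fall back to any oscillatory component
    k = int(np.argmax(np.where(in_win, np.abs(spec), -np.inf)))
    tau0 = float(np.clip(periods[k], lo, hi))
    amp0 = 2.0 * np.abs(spec[k]) / resid.size
    phi0 = float((-np.angle(spec[k]) / (2 * np.pi * freqs[k]) + t[0]) % tau0)

    def model(tt, c0, c1, A, tau, phi):
        return c0 + c1 * tt + A * np.cos(2 * np.pi * (tt - phi) / tau)

    p0 = [off0, slope0, max(amp0, 1e-12), tau0, phi0]
    bounds = (
        [-np.inf, -np.inf, 0.0, lo, -np.inf],
        [np.inf, np.inf, np.inf, hi, np.inf],
    )
    try:
        popt, pcov = optimize.curve_fit(model, t, v, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        warnings.warn("cosine fit diverged; RAE reported as 1", FitDivergenceWarning,
                      stacklevel=2)
        return NllsFit(np.nan, np.nan, np.nan, tau0, np.nan, np.nan, n_obs=t.size,
                       converged=False)
    amp_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    c0, c1, A, tau, phi = popt
    return NllsFit(float(c0), float(c1), float(A), float(tau), float(phi % tau),
                   amp_se, n_obs=t.size)


def rae(fit: NllsFit, confidence: float = 0.95) -> float:
    """Relative amplitude error of a cosine fit, clipped to [0, 1].

    Following the FFT-NLLS convention, the amplitude error is half the width
    of the ``confidence`` interval on the fitted amplitude (the t quantile
    times the curvature-based standard error); RAE is that error divided by
    the amplitude.  0 marks a perfectly determined rhythm, 1 an amplitude
    indistinguishable from zero.
    """
    if not fit.converged or not np.isfinite(fit.amplitude) or fit.amplitude <= 0:
        return 1.0
    dof = max(fit.n_obs - 5, 1)
    half_width = stats.t.ppf(0.5 + confidence / 2.0, dof) * fit.amplitude_se
    return float(np.clip(half_width / fit.amplitude, 0.0, 1.0))


def rae_normalized(rae_treatment: float, rae_baseline: float) -> float:
    """Treatment RAE expressed relative to the baseline RAE."""
    if rae_baseline <= 0:
        raise ValueError("baseline RAE must be positive to normalize")
    return float(rae_treatment / rae_baseline)


# ---------------------------------------------------------------------------
# circular statistics and circadian-time mapping
# ---------------------------------------------------------------------------

def rayleigh(phases_ct: Sequence[float]) -> tuple[float, float, float]:
    """Rayleigh test of phase concentration on the 24 h circle.

    Returns ``(R, p, mean_phase_ct)`` where R is the mean resultant length
    and p the standard series approximation of the tail probability of
    Z = n R**2.
    """
    phases = np.asarray(phases_ct, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least two phases")
    theta = 2 * np.pi * phases / 24.0
    c, s = np.mean(np.cos(theta)), np.mean(np.sin(theta))
    r = float(np.hypot(c, s))
    z = n * r * r
    p = np.exp(-z) * (
        1
        + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    p = float(np.clip(p, 0.0, 1.0))
    mean_ct = float((np.arctan2(s, c) * 24.0 / (2 * np.pi)) % 24.0)
    return r, p, mean_ct


def assign_ct(
    trace_or_times,
    reference_peak_time_h: float,
    reference_ct: float = 6.0,
    period_h: float = 24.0,
) -> np.ndarray:
    """Map recording time to circadian time anchored at a reference peak.

    The reference peak (by convention the first neuronal calcium peak) is
    assigned ``reference_ct`` and time advances at 24 CT-hours per period.
    """
    t = trace_or_times.time_h if isinstance(trace_or_times, Trace) else np.asarray(
        trace_or_times, dtype=float
    )
    return (reference_ct + (t - reference_peak_time_h) * 24.0 / period_h) % 24.0


# ---------------------------------------------------------------------------
# window integration and cohort alignment
# ---------------------------------------------------------------------------

def _trapz_between(t: np.ndarray, v: np.ndarray, a: float, b: float) -> float:
    inside = (t > a) & (t < b)
    tt = np.concatenate(([a], t[inside], [b]))
    vv = np.concatenate(([np.interp(a, t, v)], v[inside], [np.interp(b, t, v)]))
    return float(np.trapezoid(vv, tt))


def integrate_24h(trace: Trace, start_h: float) -> np.ndarray:
    """Trapezoidal integrals of the signal over consecutive 24 h windows.

    Windows start at ``start_h``; a trailing partial window is dropped.
    """
    t, v = trace.time_h, trace.value
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    n_windows = int(np.floor((t[-1] - start_h) / 24.0 + 1e-9))
    if n_windows < 1:
        raise ValueError("no complete 24 h window in the recording")
    return np.array(
        [
            _trapz_between(t, v, start_h + 24.0 * m, start_h + 24.0 * (m + 1))
            for m in range(n_windows)
        ]
    )


def pseudo_align(
    traces: Sequence[Trace],
    reference_peak_per_trace: Sequence[float | None],
    max_gap_factor: float = 1.5,
) -> pd.DataFrame:
    """Align traces on their reference peaks and average them.

    Each trace is shifted so its reference peak sits at t = 0, resampled by
    linear interpolation onto a common grid at the coarsest input step, and
    averaged.  Samples excluded from a trace (NaN, e.g. treatment artifacts)
    propagate as gaps rather than being interpolated across when the gap
    exceeds ``max_gap_factor`` sampling steps.  Returns a frame with columns
    ``time_h, mean, sem, n``.
    """
    pairs = []
    for i, (tr, ref) in enumerate(zip(traces, reference_peak_per_trace)):
        if ref is None or not np.isfinite(ref):
            warnings.warn(f"trace {i} has no reference peak; excluded", UserWarning,
                          stacklevel=2)
            continue
        pairs.append((tr, float(ref)))
    if len(pairs) < 2:
        raise ValueError("need at least two traces with reference peaks")

    dt = max(tr.dt_h for tr, _ in pairs)
    start = max(tr.time_h[0] - ref for tr, ref in pairs)
    end = min(tr.time_h[-1] - ref for tr, ref in pairs)
    grid = np.arange(start, end + dt / 2, dt)

    cols = []
    for tr, ref in pairs:
        t = tr.time_h - ref
        ok = np.isfinite(tr.value)
        y = np.interp(grid, t[ok], tr.value[ok])
        # blank out grid points bridging an excluded stretch
        gap_limit = max_gap_factor * tr.dt_h
        tok = t[ok]
        left = np.searchsorted(tok, grid, side="right") - 1
        left = np.clip(left, 0, tok.size - 2)
        spacing = tok[left + 1] - tok[left]
        y = np.where(spacing > gap_limit, np.nan, y)
        y[(grid < tok[0]) | (grid > tok[-1])] = np.nan
        cols.append(y)

    mat = np.vstack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        n = np.sum(np.isfinite(mat), axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame({"time_h": grid, "mean": mean, "sem": sem, "n": n})


# ---------------------------------------------------------------------------
# one-call summary
# ---------------------------------------------------------------------------

def analyze(
    trace: Trace,
    min_separation_h: float = 16.0,
    min_prominence_frac: float = 0.2,
    period_window_h: tuple[float, float] = (18.0, 30.0),
) -> CycleMetrics:
    """Run the standard metric battery on an epoch-annotated trace."""
    peaks = find_peaks_troughs(trace, min_separation_h, min_prominence_frac)
    out = CycleMetrics()
    base = trace.epochs.get("baseline")
    treat = trace.epochs.get("treatment")
    wash = trace.epochs.get("washout")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        if base is not None:
            out.period_baseline_h = compute_period(peaks, base)
            out.rae_baseline = rae(fit_fft_nlls(trace, period_window_h, base))
        if treat is not None:
            out.period_treatment_h = compute_period(peaks, treat)
            out.delta_period_h = delta_period(out.period_baseline_h, out.period_treatment_h)
            out.normalized_amplitudes = cycle_amplitudes(peaks, treat[0])
            out.phase_shift_h = phase_shift(peaks, out.period_baseline_h, treat[0])
            try:
                out.rae_treatment = rae(fit_fft_nlls(trace, period_window_h, treat))
                out.rae_normalized = rae_normalized(out.rae_treatment, out.rae_baseline)
            except ValueError:
                pass
        out.ba_ratios = ba_ratio(peaks)
        if wash is not None:
            out.steady_state_ba = steady_state_ba(peaks, wash[0])
    return out
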
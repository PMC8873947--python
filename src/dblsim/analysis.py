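"""Spike-train feature extraction and spectral analysis of voltage traces.

Implements the measures used to characterize the depolarization-baseline
phenomenon: spike detection, the DBL itself (mean of the minimum voltage
between successive spikes), derivative-criterion spike thresholds,
depolarization-block detection, f-I / DBL-vs-current curves, an emulation of
the experimental acquisition chain (causal 4-pole Bessel low-pass then
resampling to the recording rate), and normalized ensemble Welch power
spectra.  The functions operate on plain sampled traces, so they apply to
real recordings loaded from delimited files as well as to simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "VoltageTrace",
    "SpikeFeatures",
    "detect_spikes",
    "compute_dbl",
    "spike_threshold",
    "detect_block",
    "extract_features",
    "acquisition_filter",
    "bessel_lowpass",
    "psd_ensemble",
    "fi_and_dbl_curves",
]

SPIKE_HEIGHT_MV = -10.0       # minimum peak height for a detected spike
SPIKE_SEPARATION_MS = 2.0     # minimum separation between detected peaks
THRESHOLD_DVDT = 20.0         # mV/ms derivative criterion for spike threshold
BLOCK_LEVEL_MV = -30.0        # plateau level defining depolarization block
BLOCK_MIN_MS = 100.0          # minimum spikeless plateau duration


@dataclass
class VoltageTrace:
    """A sampled membrane-potential trace.

    ``stim_window`` is the (start, end) of the stimulus in ms; feature
    extraction restricts itself to it when it is set (non-degenerate).
    """

    dt: float
    v: np.ndarray
    stim_window: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("trace contains non-finite samples")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.v)) * self.dt

    def window_slice(self) -> slice:
        t0, t1 = self.stim_window
        if t1 <= t0:
            return slice(0, len(self.v))
        return slice(int(round(t0 / self.dt)), int(round(t1 / self.dt)) + 1)


@dataclass
class SpikeFeatures:
    """Features of one spike train."""

    spike_times: np.ndarray       # ms
    peaks: np.ndarray             # mV
    thresholds: np.ndarray        # mV (NaN where the criterion was never met)
    isis: np.ndarray              # ms
    mean_frequency: float         # Hz over the stimulus window
    dbl: float                    # mV; NaN when < 2 spikes
    block: bool

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def detect_spikes(
    trace: VoltageTrace,
    height: float = SPIKE_HEIGHT_MV,
    separation_ms: float = SPIKE_SEPARATION_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect action potentials as local maxima above ``height``.

    Returns (times_ms, peak_values).  Detection is restricted to the stimulus
    window when one is set.
    """
    sl = trace.window_slice()
    v = trace.v[sl]
    distance = max(1, int(round(separation_ms / trace.dt)))
    idx, props = signal.find_peaks(v, height=height, distance=distance)
    times = (idx + sl.start) * trace.dt
    return times, v[idx]


def compute_dbl(trace: VoltageTrace, spike_times: np.ndarray) -> float:
    """Depolarization baseline: mean of the minimum voltage between successive spikes.

    Intervals run peak to peak.  Returns NaN when fewer than 2 spikes were
    detected (the quantity is undefined).
    """
    if len(spike_times) < 2:
        return float("nan")
    idx = np.round(np.asarray(spike_times) / trace.dt).astype(int)
    minima = [trace.v[i0:i1 + 1].min() for i0, i1 in zip(idx[:-1], idx[1:])]
    return float(np.mean(minima))


def spike_threshold(
    trace: VoltageTrace,
    spike_time: float,
    dvdt_crit: float = THRESHOLD_DVDT,
    lookback_ms: float = 10.0,
) -> float:
    """Voltage at spike initiation: last upward crossing of dV/dt = ``dvdt_crit``
    before the peak.  Returns NaN if the criterion is never met in the
    ``lookback_ms`` window before the spike."""
    ip = int(round(spike_time / trace.dt))
    i0 = max(0, ip - int(round(lookback_ms / trace.dt)))
    if ip - i0 < 2:
        return float("nan")
    seg = trace.v[i0:ip + 1]
    dvdt = np.gradient(seg, trace.dt)
    above = dvdt >= dvdt_crit
    crossings = np.flatnonzero(above[1:] & ~above[:-1])
    if len(crossings) == 0:
        return float("nan") if not above[0] else float(seg[0])
    i = crossings[-1]
    # linear interpolation of the crossing voltage
    f = (dvdt_crit - dvdt[i]) / (dvdt[i + 1] - dvdt[i])
    return float(seg[i] + f * (seg[i + 1] - seg[i]))


def detect_block(
    trace: VoltageTrace,
    spike_times: np.ndarray,
    level: float = BLOCK_LEVEL_MV,
    min_ms: float = BLOCK_MIN_MS,
) -> bool:
    """Depolarization block: the trace stays above ``level`` continuously for at
    least ``min_ms`` inside the stimulus window without an intervening spike."""
    sl = trace.window_slice()
    above = trace.v[sl] > level
    spike_idx = set(np.round(np.asarray(spike_times) / trace.dt).astype(int) - sl.start)
    min_n = int(round(min_ms / trace.dt))
    run = 0
    for i, a in enumerate(above):
        if a and i not in spike_idx:
            run += 1
            if run >= min_n:
                return True
        else:
            run = 0
    return False


def extract_features(trace: VoltageTrace) -> SpikeFeatures:
    """All spike-train features of one trace."""
    times, peaks = detect_spikes(trace)
    thresholds = np.array([spike_threshold(trace, t) for t in times])
    isis = np.diff(times)
    t0, t1 = trace.stim_window
    dur = (t1 - t0) if t1 > t0 else len(trace.v) * trace.dt
    freq = len(times) / dur * 1000.0
    return SpikeFeatures(
        spike_times=times,
        peaks=peaks,
        thresholds=thresholds,
        isis=isis,
        mean_frequency=freq,
        dbl=compute_dbl(trace, times),
        block=detect_block(trace, times),
    )


# ---------------------------------------------------------------------------
# acquisition chain & spectra
# ---------------------------------------------------------------------------

def bessel_lowpass(trace: VoltageTrace, cutoff_khz: float, order: int = 4) -> VoltageTrace:
    """Causal ``order``-pole Bessel low-pass at ``cutoff_khz``, at the trace's own rate.

    Initial filter state is the steady-state response to the first sample, so
    a DC trace passes through unchanged.
    """
    fs = 1.0 / trace.dt  # kHz
    if cutoff_khz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_khz} kHz >= Nyquist {fs / 2} kHz of the trace")
    sos = signal.bessel(order, cutoff_khz, btype="low", fs=fs, output="sos", norm="mag")
    zi = signal.sosfilt_zi(sos) * trace.v[0]
    y, _ = signal.sosfilt(sos, trace.v, zi=zi)
    return VoltageTrace(dt=trace.dt, v=y, stim_window=trace.stim_window,
                        meta={**trace.meta, "filter_khz": cutoff_khz})


def acquisition_filter(
    trace: VoltageTrace, cutoff_khz: float = 2.0, sample_khz: float = 10.0
) -> VoltageTrace:
    """Emulate the recording chain: Bessel low-pass then resample.

    Raises on aliasing risk (cutoff at or above the output Nyquist rate).
    """
    if cutoff_khz >= sample_khz / 2:
        raise ValueError(
            f"cutoff {cutoff_khz} kHz >= output Nyquist {sample_khz / 2} kHz: aliasing risk"
        )
    filtered = bessel_lowpass(trace, cutoff_khz)
    dt_out = 1.0 / sample_khz  # ms
    t_out = np.arange(0.0, trace.t[-1] + 1e-12, dt_out)
    v_out = np.interp(t_out, filtered.t, filtered.v)
    return VoltageTrace(dt=dt_out, v=v_out, stim_window=trace.stim_window,
                        meta={**trace.meta, "filter_khz": cutoff_khz, "sample_khz": sample_khz})


def psd_ensemble(
    traces, fmax_hz: float | None = None, segment_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized average power spectral density of an ensemble of traces.

    Each trace's Welch PSD (Hann segments of ``segment_s`` seconds, 50%
    overlap) is normalized to unit total power before averaging, so the result
    reflects the *distribution* of power over frequency, not its magnitude.
    Returns (freqs_Hz, mean_normalized_psd).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("empty ensemble")
    n = len(traces[0].v)
    if any(len(tr.v) != n for tr in traces):
        raise ValueError("traces must have equal lengths")
    fs = 1000.0 / traces[0].dt  # Hz
    nperseg = int(round(segment_s * fs))
    if nperseg > n:
        raise ValueError(
            f"trace too short for {segment_s}-s Welch segments ({n} samples at {fs} Hz)"
        )
    psds = []
    for tr in traces:
        f, p = signal.welch(tr.v - tr.v.mean(), fs=fs, window="hann",
                            nperseg=nperseg, noverlap=nperseg // 2)
        total = np.trapezoid(p, f)
        psds.append(p / total)
    f_all = f
    mean_psd = np.mean(psds, axis=0)
    if fmax_hz is not None:
        keep = f_all <= fmax_hz
        return f_all[keep], mean_psd[keep]
    return f_all, mean_psd


def fi_and_dbl_curves(sweep_results) -> pd.DataFrame:
    """f-I, DBL-vs-current and threshold-vs-current curves from a sweep.

    ``sweep_results`` is a sequence of run results (``RunResult``); returns one
    row per amplitude with mean firing frequency (Hz), DBL (mV, NaN when
    undefined), mean spike threshold (mV) and the block flag.
    """
    rows = []
    for res in sweep_results:
        feats = extract_features(res.soma_trace())
        rows.append({
            "amplitude_nA": res.amplitude,
            "n_spikes": feats.n_spikes,
            "frequency_Hz": feats.mean_frequency,
            "dbl_mV": feats.dbl,
            "threshold_mV": float(np.nanmean(feats.thresholds)) if feats.n_spikes else float("nan"),
            "block": feats.block,
        })
    return pd.DataFrame(rows)
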
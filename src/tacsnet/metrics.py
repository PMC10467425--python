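"""Spectral and connectivity read-outs of simulated activity.

Power spectral densities are Welch estimates (2 s Hann segments, 50% overlap,
zero-padded to a 0.125 Hz grid) restricted to 0-45 Hz and normalized by total
2-45 Hz power, mirroring the usual normalization of resting-state spectra.
Phase-locking values are computed from instantaneous phase differences of the
analytic signal after zero-phase band-pass filtering (4th-order Butterworth,
alpha band by default, 1 s edge trim), pooled over time samples.  The
functional-connectivity fit is the Pearson correlation of the vectorized
strictly-upper-triangular PLV matrices, and the working point is the coupling
factor maximizing that fit subject to a mean-PLV ceiling and alpha-band node
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as ssig
from scipy.stats import pearsonr

from .engine import SimulationResult

__all__ = [
    "SpectralSummary",
    "WorkingPoint",
    "NoFeasibleWorkingPoint",
    "psd",
    "band_power",
    "plv",
    "fc_matrix",
    "fc_fit",
    "select_working_point",
    "iaf",
    "ALPHA_BAND",
]

ALPHA_BAND = (8.0, 12.0)
FMAX_HZ = 45.0
NORM_BAND = (2.0, 45.0)
PEAK_BAND = (2.0, 45.0)
GRID_RES_HZ = 0.125


class NoFeasibleWorkingPoint(RuntimeError):
    """No candidate satisfies the PLV ceiling and alpha-frequency filter."""


@dataclass
class SpectralSummary:
    """Power density on a 0-45 Hz grid with its peak frequency.

    ``power`` is normalized to unit total 2-45 Hz power (the convention for
    comparing spectral shape across subjects); ``raw_power`` keeps the
    unnormalized Welch density (pA^2/Hz), the scale on which absolute
    band-power changes of a single model are measured.
    """

    freqs: np.ndarray
    power: np.ndarray
    peak_freq: float
    raw_power: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.raw_power is None:
            self.raw_power = self.power
        else:
            self.raw_power = np.asarray(self.raw_power, float)


@dataclass
class WorkingPoint:
    coupling: float
    r: float
    mean_plv: float
    peak_freqs: np.ndarray


def psd(series: np.ndarray, dt_ms: float, seg_s: float = 2.0) -> SpectralSummary:
    """Welch PSD of one time series sampled at ``1000/dt_ms`` Hz.

    Requires at least 2 s of samples.  The peak frequency is the density
    argmax within 2-45 Hz (excluding the DC bin region), and the returned
    density is normalized to unit 2-45 Hz power.
    """
    series = np.asarray(series, float)
    fs = 1000.0 / dt_ms
    nperseg = int(round(seg_s * fs))
    if series.size < nperseg:
        raise ValueError("insufficient data: need at least 2 s of samples")
    nfft = int(round(fs / GRID_RES_HZ))
    nfft = max(nfft, nperseg)
    freqs, pxx = ssig.welch(
        series, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, nfft=nfft, detrend="constant",
    )
    keep = freqs <= FMAX_HZ
    freqs, pxx = freqs[keep], pxx[keep]
    norm_mask = (freqs >= NORM_BAND[0]) & (freqs <= NORM_BAND[1])
    total = np.trapezoid(pxx[norm_mask], freqs[norm_mask])
    norm = pxx / total if total > 0 else pxx
    peak_mask = (freqs >= PEAK_BAND[0]) & (freqs <= PEAK_BAND[1])
    peak_freq = float(freqs[peak_mask][np.argmax(norm[peak_mask])])
    return SpectralSummary(freqs=freqs, power=norm, peak_freq=peak_freq,
                           raw_power=pxx)


def band_power(spec: SpectralSummary, center: float, halfwidth: float,
               normalized: bool = True) -> float:
    """Trapezoid integral of the density over ``center +/- halfwidth``.

    ``normalized=False`` integrates the unnormalized density instead, the
    scale on which stimulation-induced power changes of one model are
    expressed.
    """
    lo, hi = center - halfwidth, center + halfwidth
    if lo < spec.freqs[0] or hi > spec.freqs[-1]:
        raise ValueError("band lies outside the spectral grid")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    dens = spec.power if normalized else spec.raw_power
    return float(np.trapezoid(dens[mask], spec.freqs[mask]))


def _band_phase(series: np.ndarray, band: tuple, fs: float, trim_s: float) -> np.ndarray:
    sos = ssig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filtered = ssig.sosfiltfilt(sos, series)
    phase = np.angle(ssig.hilbert(filtered))
    trim = int(round(trim_s * fs))
    return phase[trim: len(phase) - trim] if trim > 0 else phase


def plv(
    series_a: np.ndarray,
    series_b: np.ndarray,
    band: tuple = ALPHA_BAND,
    dt_ms: float = 1.0,
    trim_s: float = 1.0,
) -> float:
    """Phase-locking value in [0, 1]: magnitude of the time-averaged complex
    exponential of the instantaneous phase difference in ``band``."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    fs = 1000.0 / dt_ms
    pa = _band_phase(a, band, fs, trim_s)
    pb = _band_phase(b, band, fs, trim_s)
    return float(np.abs(np.mean(np.exp(1j * (pa - pb)))))


def fc_matrix(result: SimulationResult, band: tuple = ALPHA_BAND) -> np.ndarray:
    """Region x region PLV matrix of the simulated LFPs (sFC)."""
    R = result.lfp.shape[0]
    if R < 2:
        raise ValueError("functional connectivity needs at least 2 regions")
    fs = result.fs_hz
    phases = [_band_phase(result.lfp[k], band, fs, 1.0) for k in range(R)]
    fc = np.eye(R)
    for i in range(R):
        for j in range(i + 1, R):
            val = float(np.abs(np.mean(np.exp(1j * (phases[i] - phases[j])))))
            fc[i, j] = fc[j, i] = val
    return fc


def fc_fit(sim_fc: np.ndarray, target_fc: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper-triangular entries."""
    sim_fc = np.asarray(sim_fc, float)
    target_fc = np.asarray(target_fc, float)
    if sim_fc.shape != target_fc.shape:
        raise ValueError("FC matrices must have the same shape")
    iu = np.triu_indices_from(sim_fc, k=1)
    r, _ = pearsonr(sim_fc[iu], target_fc[iu])
    return float(r)


def iaf(spec: SpectralSummary, band: tuple = ALPHA_BAND) -> float:
    """Individual alpha frequency: density argmax within the alpha band."""
    mask = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    return float(spec.freqs[mask][np.argmax(spec.power[mask])])


def tidy_metrics(result: SimulationResult, trial: int = 0,
                 band: tuple = ALPHA_BAND) -> "pd.DataFrame":
    """Per-region spectral read-outs as a tidy (trial, region, measure,
    value) table: peak frequency, IAF and alpha band power."""
    import pandas as pd

    rows = []
    for k, region in enumerate(result.region_ids):
        spec = psd(result.lfp[k], result.dt_ms)
        f_alpha = iaf(spec, band)
        for measure, value in (
            ("peak_freq_hz", spec.peak_freq),
            ("iaf_hz", f_alpha),
            ("alpha_band_power", band_power(spec, f_alpha, 0.5)),
        ):
            rows.append(dict(trial=trial, region=region, measure=measure,
                             value=value))
    return pd.DataFrame(rows)


def scan_to_frame(candidates: list) -> "pd.DataFrame":
    """Working-point scan as a table over the coupling factor."""
    import pandas as pd

    return pd.DataFrame(
        [dict(coupling=c[0], r=c[1], mean_plv=c[2],
              median_peak_hz=float(np.median(c[3]))) for c in candidates]
    )


def select_working_point(
    candidates: list,
    plv_ceiling: float = 0.8,
    freq_band: tuple = ALPHA_BAND,
) -> WorkingPoint:
    """Among candidates (coupling, r, mean_plv, peak_freqs) with mean PLV at
    or below the ceiling ("unrealistically high" synchrony excluded) and
    median node peak frequency inside ``freq_band``, return the one
    maximizing the FC fit r."""
    if not candidates:
        raise NoFeasibleWorkingPoint("empty candidate list")
    feasible = []
    for cand in candidates:
        coupling, r, mean_plv, peaks = cand
        peaks = np.asarray(peaks, float)
        med = float(np.median(peaks))
        if mean_plv <= plv_ceiling and freq_band[0] <= med <= freq_band[1]:
            feasible.append(WorkingPoint(coupling, r, mean_plv, peaks))
    if not feasible:
        raise NoFeasibleWorkingPoint(
            "no candidate satisfies the PLV ceiling and alpha-frequency filter"
        )
    return max(feasible, key=lambda wp: wp.r)
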
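"""Population-rate spectral measures and aperiodic+periodic parameterization.

The instantaneous population rate is the across-neuron average of per-neuron
Gaussian kernel density estimates of spiking.  Its Welch power spectrum is
summarized by the log-power maximum (PSD_max, f_max) and by a FOOOF-style
decomposition of the log spectrum into an aperiodic component

    log10 P(f) = b_L - chi_L * log10 f

plus one (single-peak model) or two (dual-peak model) Gaussian peaks fit in
log-power space.  Peaks whose amplitude does not exceed a significance
threshold (``peak_sig_mult`` times the SD of the aperiodic-fit residuals,
with an absolute floor) are not assigned and their parameters are NaN,
mirroring how sparse or non-rhythmic activity yields no detectable peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import welch

__all__ = [
    "SpectralConfig",
    "PopulationRate",
    "FooofFit",
    "population_rate",
    "power_spectrum",
    "fit_fooof",
    "export_spectrum",
    "SPECTRAL_CORE_NAMES",
    "SPECTRAL_DUAL_NAMES",
    "spectral_measures",
]


@dataclass(frozen=True)
class SpectralConfig:
    kernel_bw_ms: float = 2.0     # population-rate Gaussian kernel SD
    grid_dt_ms: float = 1.0       # rate grid step
    welch_segment_s: float = 2.0  # Welch segment length (50% overlap, Hann)
    band_lo_hz: float = 1.0
    band_hi_hz: float = 100.0
    peak_sig_mult: float = 2.0    # relative peak threshold (x residual SD)
    peak_min_height: float = 0.05  # absolute threshold (log10 power units)


@dataclass
class PopulationRate:
    times: np.ndarray
    rate: np.ndarray     # Hz, population average
    kernel_bw: float     # s


@dataclass
class FooofFit:
    b: float = np.nan       # broadband offset
    chi: float = np.nan     # aperiodic exponent
    peaks: list = field(default_factory=list)  # (f_G, A_G, sigma_G, beta_G)
    mae: float = np.nan
    r2: float = np.nan


def population_rate(
    trains, T: float, kernel_bw: float = 0.002, dt_grid: float = 0.001
) -> PopulationRate:
    if kernel_bw <= 0:
        raise ValueError("kernel_bw must be positive")
    spikes = [np.asarray(s, float) for s in trains]
    n_grid = max(2, int(round(T / dt_grid)))
    t = (np.arange(n_grid) + 0.5) * dt_grid
    N = max(len(spikes), 1)
    counts = np.zeros(n_grid)
    for s in spikes:
        if s.size:
            idx = np.minimum((s / dt_grid).astype(np.int64), n_grid - 1)
            np.add.at(counts, idx, 1.0)
    # reflect mode keeps the kernel mass inside [0, T): the rate integral is
    # exactly (total spike count)/N
    rate = gaussian_filter1d(counts, sigma=kernel_bw / dt_grid, mode="reflect")
    rate /= N * dt_grid
    return PopulationRate(times=t, rate=rate, kernel_bw=kernel_bw)


def power_spectrum(
    pr: PopulationRate, config: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Welch log-power spectrum of the mean-subtracted population rate.

    Returns (freqs, log_power, PSD_max, f_max, peak_defined); when the rate
    is constant the spectrum is identically zero power, PSD_max is the log
    floor and f_max falls back (flagged False) to the lowest band frequency.
    """
    dt = float(np.mean(np.diff(pr.times)))
    fs = 1.0 / dt
    nperseg = min(int(round(config.welch_segment_s * fs)), pr.rate.size)
    if nperseg < 8:
        raise ValueError("rate series too short for the Welch segment length")
    x = pr.rate - pr.rate.mean()
    f, p = welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    band = (f >= config.band_lo_hz) & (f <= config.band_hi_hz)
    f, p = f[band], p[band]
    log_p = np.log10(np.maximum(p, 1e-30))
    if np.all(p <= 0):
        return f, log_p, float(log_p.max()), float(f[0]), False
    i = int(np.argmax(log_p))
    return f, log_p, float(log_p[i]), float(f[i]), True


def _aperiodic(logf: np.ndarray, b: float, chi: float) -> np.ndarray:
    return b - chi * logf


def _robust_aperiodic(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Linear aperiodic fit, iteratively discarding high positive residuals
    so narrowband peaks do not bias the baseline."""
    mask = np.ones(y.size, dtype=bool)
    b = chi = 0.0
    for _ in range(3):
        coef = np.polyfit(logf[mask], y[mask], 1)
        b, chi = coef[1], -coef[0]
        resid = y - _aperiodic(logf, b, chi)
        thr = np.percentile(resid[mask], 75)
        new_mask = resid <= max(thr, 0.0)
        if new_mask.sum() < max(4, y.size // 4) or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return float(b), float(chi)


def _gauss(x, f0, a, s):
    return a * np.exp(-0.5 * ((x - f0) / s) ** 2)


def fit_fooof(
    freqs: np.ndarray,
    log_power: np.ndarray,
    n_peaks: int = 1,
    config: SpectralConfig = SpectralConfig(),
) -> FooofFit:
    """Fit the aperiodic + n_peaks-Gaussian model to a log-power spectrum."""
    if n_peaks not in (1, 2):
        raise ValueError("n_peaks must be 1 or 2")
    freqs = np.asarray(freqs, float)
    y = np.asarray(log_power, float)
    ok = np.isfinite(y) & (freqs > 0)
    freqs, y = freqs[ok], y[ok]
    if freqs.size < 2 * n_peaks + 3 + 2:
        raise ValueError("not enough frequency bins for the requested model")
    logf = np.log10(freqs)

    b, chi = _robust_aperiodic(logf, y)
    resid = y - _aperiodic(logf, b, chi)
    sig_floor = max(config.peak_sig_mult * float(np.std(resid)), config.peak_min_height)

    peaks: list[tuple[float, float, float]] = []
    work = resid.copy()
    fspan = freqs[-1] - freqs[0]
    for _ in range(n_peaks):
        i = int(np.argmax(work))
        amp = work[i]
        if amp <= sig_floor:
            break
        p0 = (freqs[i], amp, max(fspan / 50.0, 1.0))
        try:
            popt, _ = curve_fit(
                _gauss,
                freqs,
                work,
                p0=p0,
                bounds=([freqs[0], 0.0, 0.25], [freqs[-1], 10.0 * amp, fspan]),
                maxfev=5000,
            )
        except RuntimeError:
            break
        if popt[1] <= sig_floor:
            break
        peaks.append(tuple(popt))
        work = work - _gauss(freqs, *popt)

    # joint refinement of aperiodic + accepted peaks
    if peaks:
        def model(f, *theta):
            out = _aperiodic(np.log10(f), theta[0], theta[1])
            for k in range(len(peaks)):
                out = out + _gauss(f, *theta[2 + 3 * k : 5 + 3 * k])
            return out

        p0 = [b, chi] + [v for pk in peaks for v in pk]
        lo = [-np.inf, -np.inf] + [freqs[0], 0.0, 0.25] * len(peaks)
        hi = [np.inf, np.inf] + [freqs[-1], np.inf, fspan] * len(peaks)
        try:
            popt, _ = curve_fit(model, freqs, y, p0=p0, bounds=(lo, hi), maxfev=10000)
            b, chi = float(popt[0]), float(popt[1])
            peaks = [tuple(popt[2 + 3 * k : 5 + 3 * k]) for k in range(len(peaks))]
        except RuntimeError:
            pass
        yhat = model(freqs, *([b, chi] + [v for pk in peaks for v in pk]))
    else:
        yhat = _aperiodic(logf, b, chi)

    err = y - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else np.nan
    fit = FooofFit(
        b=b,
        chi=chi,
        peaks=[(f0, a, s, a / s) for (f0, a, s) in peaks],
        mae=float(np.mean(np.abs(err))),
        r2=r2,
    )
    return fit


def export_spectrum(path, freqs: np.ndarray, log_power: np.ndarray) -> None:
    """Write a spectrum as two-column CSV (frequency_hz, log10_power)."""
    arr = np.column_stack([freqs, log_power])
    np.savetxt(path, arr, delimiter=",", header="frequency_hz,log10_power",
               comments="")


SPECTRAL_CORE_NAMES = (
    "PSD_max",
    "f_max",
    "b_L",
    "chi_L",
    "f_G",
    "A_G",
    "sigma_G",
    "beta_G",
    "MAE",
    "R2",
)

SPECTRAL_DUAL_NAMES = (
    "b_L_2p",
    "chi_L_2p",
    "f_G_2p1",
    "A_G_2p1",
    "sigma_G_2p1",
    "beta_G_2p1",
    "f_G_2p2",
    "A_G_2p2",
    "sigma_G_2p2",
    "beta_G_2p2",
    "MAE_2p",
    "R2_2p",
    "R2_ratio",
)


def spectral_measures(
    trains, T: float, config: SpectralConfig = SpectralConfig(), dual: bool = True
) -> dict[str, float]:
    """All spectral measures of a multineuron train (NaN where unassigned)."""
    out = {name: np.nan for name in SPECTRAL_CORE_NAMES}
    if dual:
        out.update({name: np.nan for name in SPECTRAL_DUAL_NAMES})
    pr = population_rate(
        trains, T, kernel_bw=config.kernel_bw_ms / 1000.0,
        dt_grid=config.grid_dt_ms / 1000.0,
    )
    try:
        f, log_p, psd_max, f_max, defined = power_spectrum(pr, config)
    except ValueError:
        return out
    out["PSD_max"] = psd_max
    out["f_max"] = f_max if defined else np.nan
    if not defined:
        return out
    try:
        fit1 = fit_fooof(f, log_p, n_peaks=1, config=config)
    except ValueError:
        return out
    out["b_L"], out["chi_L"] = fit1.b, fit1.chi
    out["MAE"], out["R2"] = fit1.mae, fit1.r2
    if fit1.peaks:
        out["f_G"], out["A_G"], out["sigma_G"], out["beta_G"] = fit1.peaks[0]
    if not dual:
        return out
    fit2 = fit_fooof(f, log_p, n_peaks=2, config=config)
    out["b_L_2p"], out["chi_L_2p"] = fit2.b, fit2.chi
    out["MAE_2p"], out["R2_2p"] = fit2.mae, fit2.r2
    if fit1.r2 and np.isfinite(fit1.r2) and fit1.r2 != 0:
        out["R2_ratio"] = fit2.r2 / fit1.r2
    pk = list(fit2.peaks)
    if pk:
        if len(pk) == 2:
            # first peak: center frequency closest to the single-peak center
            ref = fit1.peaks[0][0] if fit1.peaks else None
            if ref is not None and abs(pk[1][0] - ref) < abs(pk[0][0] - ref):
                pk = [pk[1], pk[0]]
        out["f_G_2p1"], out["A_G_2p1"], out["sigma_G_2p1"], out["beta_G_2p1"] = pk[0]
        if len(pk) == 2:
            out["f_G_2p2"], out["A_G_2p2"], out["sigma_G_2p2"], out["beta_G_2p2"] = pk[1]
    return out
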
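"""Time- and frequency-domain heart rate variability metrics.

Time domain: RR mean, SDRR (sample SD, N-1 denominator), RMSSD, pNN50.
Frequency domain: absolute power (ms^2) of the RR tachogram integrated over
the LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands, following Task-Force-style
conventions: the unevenly sampled tachogram is resampled at 4 Hz by cubic
interpolation, detrended, and its power spectral density estimated by a
Welch segment-averaged Hann-windowed periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import interpolate, signal

from .errors import InsufficientDataError
from .rr_signal import RRSeries

__all__ = [
    "TimeDomainMetrics",
    "SpectralConfig",
    "HRVMetrics",
    "time_domain_metrics",
    "frequency_domain_metrics",
    "hrv_metrics",
]


@dataclass(frozen=True)
class TimeDomainMetrics:
    rr_mean: float  # ms
    sdrr: float  # ms
    rmssd: float  # ms
    pnn50: float  # %

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class SpectralConfig:
    """Configuration of the spectral HRV estimator.

    ``resample_rate`` must exceed twice the upper HF edge so the band of
    interest sits below the Nyquist frequency.
    """

    resample_rate: float = 4.0  # Hz
    segment_length: float = 120.0  # s
    overlap: float = 0.5  # fraction of segment
    lf_band: tuple[float, float] = (0.04, 0.15)  # Hz
    hf_band: tuple[float, float] = (0.15, 0.40)  # Hz
    detrend: str = "linear"  # {none, linear}

    def __post_init__(self) -> None:
        for lo, hi in (self.lf_band, self.hf_band):
            if not lo < hi:
                raise ValueError("band lower edge must be below upper edge")
        if self.resample_rate <= 2 * self.hf_band[1]:
            raise ValueError("resample_rate must exceed twice the HF upper edge")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.detrend not in ("none", "linear"):
            raise ValueError(f"unknown detrend mode {self.detrend!r}")


@dataclass(frozen=True)
class HRVMetrics:
    """The full per-segment HRV parameter set."""

    rr_mean: float  # ms
    sdrr: float  # ms
    rmssd: float  # ms
    pnn50: float  # %
    lf_power: float  # ms^2
    hf_power: float  # ms^2

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def time_domain_metrics(rr: RRSeries) -> TimeDomainMetrics:
    """Compute RR mean, SDRR, RMSSD and pNN50 over one recording segment.

    Beats labelled ``artifact`` are excluded (filtered recordings carry
    ``interpolated`` replacements instead, which are included).
    """
    x = rr.normal_intervals()
    if x.size < 2:
        raise InsufficientDataError(
            f"time-domain metrics need >= 2 beats, got {x.size}"
        )
    diffs = np.diff(x)
    return TimeDomainMetrics(
        rr_mean=float(x.mean()),
        sdrr=float(x.std(ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / diffs.size),
    )


def resample_tachogram(
    rr: RRSeries, rate: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-interpolate the (beat time, RR) tachogram onto a uniform grid.

    Returns ``(times, rr_ms)``. With fewer than 4 beats the cubic spline is
    undefined; callers guard via duration checks first.
    """
    t = rr.beat_times
    x = rr.intervals
    if len(rr) < 4:
        raise InsufficientDataError("tachogram resampling needs >= 4 beats")
    grid = np.arange(t[0], t[-1], 1.0 / rate)
    spline = interpolate.interp1d(t, x, kind="cubic", assume_sorted=True)
    return grid, spline(grid)


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (f >= band[0]) & (f <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def frequency_domain_metrics(
    rr: RRSeries, cfg: SpectralConfig | None = None
) -> tuple[float, float]:
    """Integrated LF and HF power (ms^2) of the RR tachogram.

    The recording must span at least one Welch segment
    (``cfg.segment_length`` seconds).
    """
    cfg = cfg or SpectralConfig()
    if len(rr) < 4 or rr.beat_times[-1] - rr.beat_times[0] < cfg.segment_length:
        raise InsufficientDataError(
            f"spectral analysis needs >= {cfg.segment_length:g} s of beats"
        )
    _, x = resample_tachogram(rr, cfg.resample_rate)
    if cfg.detrend == "linear":
        x = signal.detrend(x, type="linear")
    else:
        x = x - x.mean()
    nperseg = int(round(cfg.segment_length * cfg.resample_rate))
    f, psd = signal.welch(
        x,
        fs=cfg.resample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(cfg.overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return _band_power(f, psd, cfg.lf_band), _band_power(f, psd, cfg.hf_band)


def total_power(rr: RRSeries, cfg: SpectralConfig | None = None) -> float:
    """Integrated PSD power over the full spectrum (ms^2); sanity companion
    to the band powers (approximates the resampled tachogram's variance)."""
    cfg = cfg or SpectralConfig()
    lf, hf = frequency_domain_metrics(rr, cfg)  # validates inputs
    _, x = resample_tachogram(rr, cfg.resample_rate)
    if cfg.detrend == "linear":
        x = signal.detrend(x, type="linear")
    nperseg = int(round(cfg.segment_length * cfg.resample_rate))
    f, psd = signal.welch(
        x,
        fs=cfg.resample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(cfg.overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return float(np.trapezoid(psd, f))


def hrv_metrics(rr: RRSeries, cfg: SpectralConfig | None = None) -> HRVMetrics:
    """Full HRV parameter set for one recording segment."""
    td = time_domain_metrics(rr)
    lf, hf = frequency_domain_metrics(rr, cfg)
    return HRVMetrics(
        rr_mean=td.rr_mean,
        sdrr=td.sdrr,
        rmssd=td.rmssd,
        pnn50=td.pnn50,
        lf_power=lf,
        hf_power=hf,
    )
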
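"""Transfer function analysis (TFA) of dynamic cerebral autoregulation.

Estimates the linear relation between arterial blood pressure (input) and
cerebral blood-flow velocity (output) by Welch cross-spectral analysis and
reduces it to three band-averaged read-outs over 0.06-0.12 Hz:

* phase difference (degrees; positive = CBFV leads ABP, the signature of
  active autoregulation; lower phase = impaired autoregulation),
* gain (|H|; by default with CBFV expressed as percent of its own mean,
  giving %/mmHg),
* magnitude-squared coherence (signal-to-noise / linearity indicator).

Bins whose coherence falls below the validity cutoff (0.34 for 5 windows
at the 5% significance level, a cited constant) are excluded from the
phase/gain averages; a recording with no valid bin is flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import UniformSignal


@dataclass(frozen=True)
class TFAConfig:
    band_lo_hz: float = 0.06
    band_hi_hz: float = 0.12
    n_windows: int = 5
    overlap: float = 0.5
    taper: str = "hann"
    detrend: str = "linear"          # linear | mean | none
    coherence_cutoff: float = 0.34   # cited critical value, 5 windows, alpha=5%
    resample_hz: float = 10.0
    gain_normalization: str = "percent_of_mean_cbfv"  # or "absolute"

    def validate(self) -> None:
        if not 0 < self.band_lo_hz < self.band_hi_hz <= self.resample_hz / 2:
            raise ValueError("band must satisfy 0 < lo < hi <= resample_hz/2")
        if self.n_windows < 2:
            raise ValueError("n_windows must be at least 2")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if not 0 <= self.coherence_cutoff <= 1:
            raise ValueError("coherence_cutoff must lie in [0, 1]")
        if self.detrend not in ("linear", "mean", "none"):
            raise ValueError("detrend must be linear, mean or none")
        if self.gain_normalization not in ("percent_of_mean_cbfv", "absolute"):
            raise ValueError("unknown gain_normalization")

    def window_samples(self, n_total: int) -> tuple[int, int]:
        """Segment length and overlap (samples) giving ``n_windows`` segments.

        Total length N split into w windows at fractional overlap v uses
        segments of N / (1 + (w-1)(1-v)) samples; for 600 s, 5 windows and
        50% overlap that is 200-s segments (0.005 Hz resolution).
        """
        nperseg = int(n_total // (1 + (self.n_windows - 1) * (1 - self.overlap)))
        noverlap = int(np.ceil(nperseg * self.overlap))
        return nperseg, noverlap


@dataclass(frozen=True)
class SpectralEstimate:
    """Welch auto/cross spectra and coherence for one signal pair."""

    freqs: np.ndarray
    Sxx: np.ndarray
    Syy: np.ndarray
    Sxy: np.ndarray          # complex; phase positive when y leads x
    coherence: np.ndarray    # magnitude-squared
    n_windows_used: int


@dataclass(frozen=True)
class TFAResult:
    """Band-averaged autoregulation read-outs for one recording."""

    phase_deg: float
    gain: float
    mean_coherence: float
    n_valid_bins: int
    valid: bool
    phase_in_range: bool = True  # quality flag: phase within [0, 90] degrees
    gain_units: str = "%/mmHg"


def preprocess_pair(abp: UniformSignal, cbfv: UniformSignal,
                    cfg: TFAConfig = TFAConfig()) -> tuple[UniformSignal, UniformSignal]:
    """Resample a pair to a common grid, normalize CBFV, detrend.

    The two channels are trimmed to their overlapping time span and
    linearly interpolated onto a shared grid at ``cfg.resample_hz``. Under
    percent normalization CBFV is rescaled to percent of its own mean
    (so downstream gain is %/mmHg and invariant to probe calibration).
    Detrending (linear by default) removes slow drift outside the band.
    """
    cfg.validate()
    t0 = max(abp.t0, cbfv.t0)
    t1 = min(abp.times[-1], cbfv.times[-1])
    min_dur = 2.0 / cfg.band_lo_hz
    if t1 - t0 < min_dur:
        raise ValueError("recording too short: overlapping span "
                         f"{t1 - t0:.1f} s < {min_dur:.1f} s")
    t = np.arange(t0, t1 + 0.5 / cfg.resample_hz, 1.0 / cfg.resample_hz)
    t = t[t <= t1]
    x = np.interp(t, abp.times, abp.data)
    y = np.interp(t, cbfv.times, cbfv.data)
    if cfg.gain_normalization == "percent_of_mean_cbfv":
        y = 100.0 * y / np.mean(y)
        y_units = "%"
    else:
        y_units = cbfv.units
    if cfg.detrend == "linear":
        x = sps.detrend(x, type="linear")
        y = sps.detrend(y, type="linear")
    elif cfg.detrend == "mean":
        x = x - np.mean(x)
        y = y - np.mean(y)
    return (abp.with_data(x, fs=cfg.resample_hz, t0=t0),
            cbfv.with_data(y, fs=cfg.resample_hz, t0=t0, units=y_units))


def welch_cross_spectra(x: UniformSignal, y: UniformSignal,
                        cfg: TFAConfig = TFAConfig()) -> SpectralEstimate:
    """One-sided Welch auto and cross spectral densities plus coherence."""
    cfg.validate()
    if x.n != y.n or x.fs != y.fs:
        raise ValueError("signals must share length and sampling rate")
    nperseg, noverlap = cfg.window_samples(x.n)
    if nperseg / x.fs < 1.0 / cfg.band_lo_hz:
        raise ValueError(
            f"segments of {nperseg / x.fs:.1f} s are too short to resolve "
            f"the {cfg.band_lo_hz} Hz band edge")
    step = nperseg - noverlap
    n_seg = (x.n - noverlap) // step
    if n_seg < cfg.n_windows:
        raise ValueError(
            f"only {n_seg} Welch segments available; need {cfg.n_windows}")
    detrend = {"linear": "linear", "mean": "constant", "none": False}[cfg.detrend]
    kw = dict(fs=x.fs, window=cfg.taper, nperseg=nperseg, noverlap=noverlap,
              detrend=detrend, scaling="density")
    f, Sxx = sps.welch(x.data, **kw)
    _, Syy = sps.welch(y.data, **kw)
    _, Sxy = sps.csd(x.data, y.data, **kw)
    denom = Sxx * Syy
    coh = np.zeros_like(Sxx)
    pos = denom > 0
    coh[pos] = np.abs(Sxy[pos]) ** 2 / denom[pos]
    coh = np.clip(coh, 0.0, 1.0)
    return SpectralEstimate(freqs=f, Sxx=Sxx, Syy=Syy, Sxy=Sxy,
                            coherence=coh, n_windows_used=int(n_seg))


def tfa_reduce(est: SpectralEstimate, cfg: TFAConfig = TFAConfig()) -> TFAResult:
    """Reduce a spectral estimate to band-averaged phase, gain, coherence.

    Per-bin transfer function H(f) = Sxy/Sxx. Phase angles are unwrapped
    within the (narrow) band before averaging to avoid +-180 degree
    artifacts; only bins with coherence >= cutoff enter the phase/gain
    averages, while mean coherence is reported over all band bins. The
    phase is reported raw with a quality flag when outside [0, 90] degrees
    rather than clamped.
    """
    cfg.validate()
    band = ((est.freqs >= cfg.band_lo_hz) & (est.freqs <= cfg.band_hi_hz)
            & (est.freqs > 0))
    if not np.any(band):
        raise ValueError("spectral estimate has no bins in the analysis band")
    H = est.Sxy[band] / est.Sxx[band]
    coh = est.coherence[band]
    phase = np.unwrap(np.angle(H))
    valid = coh >= cfg.coherence_cutoff
    n_valid = int(np.count_nonzero(valid))
    mean_coh = float(np.mean(coh))
    if n_valid == 0:
        return TFAResult(phase_deg=float("nan"), gain=float("nan"),
                         mean_coherence=mean_coh, n_valid_bins=0, valid=False,
                         phase_in_range=False,
                         gain_units=_gain_units(cfg))
    ph = float(np.rad2deg(np.mean(phase[valid])))
    ph = ((ph + 180.0) % 360.0) - 180.0
    if ph == -180.0:
        ph = 180.0
    gain = float(np.mean(np.abs(H[valid])))
    return TFAResult(phase_deg=ph, gain=gain, mean_coherence=mean_coh,
                     n_valid_bins=n_valid, valid=True,
                     phase_in_range=0.0 <= ph <= 90.0,
                     gain_units=_gain_units(cfg))


def _gain_units(cfg: TFAConfig) -> str:
    return "%/mmHg" if cfg.gain_normalization == "percent_of_mean_cbfv" \
        else "cm/s/mmHg"


def analyze_pair(abp: UniformSignal, cbfv: UniformSignal,
                 cfg: TFAConfig = TFAConfig()) -> TFAResult:
    """Convenience wrapper: preprocess, cross-spectra, band reduction."""
    x, y = preprocess_pair(abp, cbfv, cfg)
    return tfa_reduce(welch_cross_spectra(x, y, cfg), cfg)


def combine_hemispheres(left: TFAResult, right: TFAResult) -> TFAResult:
    """Whole-brain result as the per-subject mean of the two hemispheres."""
    if not (left.valid and right.valid):
        return TFAResult(phase_deg=float("nan"), gain=float("nan"),
                         mean_coherence=float(np.mean([left.mean_coherence,
                                                       right.mean_coherence])),
                         n_valid_bins=min(left.n_valid_bins, right.n_valid_bins),
                         valid=False, phase_in_range=False,
                         gain_units=left.gain_units)
    ph = 0.5 * (left.phase_deg + right.phase_deg)
    return TFAResult(
        phase_deg=ph,
        gain=0.5 * (left.gain + right.gain),
        mean_coherence=0.5 * (left.mean_coherence + right.mean_coherence),
        n_valid_bins=min(left.n_valid_bins, right.n_valid_bins),
        valid=True,
        phase_in_range=0.0 <= ph <= 90.0,
        gain_units=left.gain_units,
    )
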
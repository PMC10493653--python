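"""Beat-to-beat heart-rate-variability analysis.

Pipeline: ectopic detection and correction on the raw beat-interval series,
time-domain indices (mean NN, SDNN, RMSSD), and Welch spectral indices
(TP, VLF, LF, HF, normalized units, LF/HF) on the cubic-spline resampled
series. Recordings whose ectopic fraction exceeds 20% are marked excluded
and refused by the index calculators.

Conventions used throughout (documented because the field's software
packages differ on them): logs are base 10; total power is defined as
VLF + LF + HF over 0-0.40 Hz, which makes the normalized-unit identity
nLF + nHF = 100 exact; band edges are half-open [lo, hi) so no Welch bin
is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import interpolate, signal


@dataclass(frozen=True)
class NNSeries:
    """A beat-interval series (ms) with cleaning bookkeeping.

    ``corrected_positions`` holds indices the detector flagged and
    interpolated; ``injected_positions`` (optional) holds ground-truth
    ectopic indices when the series came from the synthetic generator.
    """

    intervals_ms: np.ndarray
    ectopic_fraction: float = 0.0
    corrected_positions: tuple = ()
    excluded: bool = False
    injected_positions: Optional[tuple] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals_ms",
                           np.asarray(self.intervals_ms, dtype=float))
        if np.any(self.intervals_ms <= 0):
            raise ValueError("NN intervals must all be positive")

    @property
    def n(self) -> int:
        return self.intervals_ms.size

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.intervals_ms)) / 1000.0


@dataclass(frozen=True)
class HRVConfig:
    """Settings for cleaning and spectral estimation."""

    resample_hz: float = 4.0
    interpolation: str = "cubic_spline"  # or "linear"
    taper: str = "hann"
    overlap: float = 0.5
    window_s: float = 120.0
    vlf_hi: float = 0.04
    lf_hi: float = 0.15
    hf_hi: float = 0.40
    ectopic_threshold: float = 0.20   # fractional deviation from local median
    local_window: int = 5             # beats of running-median memory
    exclusion_fraction: float = 0.20  # recording-level ectopic-rate cutoff

    def validate(self) -> None:
        if not (0 < self.vlf_hi < self.lf_hi < self.hf_hi <= self.resample_hz / 2):
            raise ValueError("band edges must satisfy "
                             "0 < vlf_hi < lf_hi < hf_hi <= resample_hz/2")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if self.interpolation not in ("cubic_spline", "linear"):
            raise ValueError("interpolation must be cubic_spline or linear")


@dataclass(frozen=True)
class HRVTimeDomain:
    mean_nn_ms: float
    sdnn_ms: float
    rmssd_ms: float
    log_sdnn: float   # log10 ms; nan when sdnn == 0
    log_rmssd: float  # log10 ms; nan when rmssd == 0


@dataclass(frozen=True)
class HRVFreqDomain:
    tp_ms2: float
    vlf_ms2: float
    lf_ms2: float
    hf_ms2: float
    log_tp: float
    log_vlf: float
    log_lf: float
    log_hf: float
    nlf: float        # LF / (TP - VLF) * 100
    nhf: float        # HF / (TP - VLF) * 100
    lf_hf_ratio: float


def clean_nn(raw, cfg: HRVConfig = HRVConfig()) -> NNSeries:
    """Detect and correct ectopic intervals in a raw beat series.

    An interval deviating more than ``cfg.ectopic_threshold`` (fractional)
    from the running median of the last ``cfg.local_window`` accepted
    intervals is flagged; flagged intervals are replaced by linear
    interpolation between the surrounding clean intervals. The recording
    is marked excluded when the flagged fraction exceeds
    ``cfg.exclusion_fraction``.
    """
    cfg.validate()
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1 or x.size < 30:
        raise ValueError("NN series too short: need at least 30 intervals")

    # seed the reference with a robust start so an ectopic first beat
    # cannot anchor the running median and cascade
    ref0 = float(np.median(x[: cfg.local_window]))
    accepted: list[float] = []
    flagged: list[int] = []
    for i, v in enumerate(x):
        ref = (float(np.median(accepted[-cfg.local_window:]))
               if accepted else ref0)
        if abs(v - ref) / ref > cfg.ectopic_threshold:
            flagged.append(i)
        else:
            accepted.append(v)

    corrected = x.copy()
    if flagged:
        good = np.setdiff1d(np.arange(x.size), flagged)
        if good.size == 0:
            raise ValueError("every interval flagged as ectopic; series unusable")
        corrected[flagged] = np.interp(np.asarray(flagged), good, x[good])

    frac = len(flagged) / x.size
    return NNSeries(
        intervals_ms=corrected,
        ectopic_fraction=frac,
        corrected_positions=tuple(flagged),
        excluded=frac > cfg.exclusion_fraction,
    )


def _require_usable(nn: NNSeries) -> None:
    if nn.excluded:
        raise ValueError(
            f"series excluded: ectopic fraction {nn.ectopic_fraction:.1%} "
            "exceeds the 20% cutoff")


def time_domain(nn: NNSeries) -> HRVTimeDomain:
    """Mean NN, SDNN (sample SD), RMSSD, and their base-10 logs."""
    _require_usable(nn)
    x = nn.intervals_ms
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d ** 2))) if d.size else 0.0
    return HRVTimeDomain(
        mean_nn_ms=mean_nn,
        sdnn_ms=sdnn,
        rmssd_ms=rmssd,
        log_sdnn=float(np.log10(sdnn)) if sdnn > 0 else float("nan"),
        log_rmssd=float(np.log10(rmssd)) if rmssd > 0 else float("nan"),
    )


def freq_domain(nn: NNSeries, cfg: HRVConfig = HRVConfig()) -> HRVFreqDomain:
    """Welch band powers of the resampled NN series.

    The series is placed on its cumulative-time axis, interpolated to
    ``cfg.resample_hz`` (cubic spline by default), mean-removed, and the
    one-sided Welch PSD is integrated over [0, vlf_hi), [vlf_hi, lf_hi),
    [lf_hi, hf_hi) Hz.
    """
    cfg.validate()
    _require_usable(nn)
    x = nn.intervals_ms
    t = np.concatenate(([0.0], np.cumsum(x)))[:-1] / 1000.0
    if t[-1] < 2 * cfg.window_s:
        raise ValueError(
            f"recording too short for spectral analysis: {t[-1]:.0f} s "
            f"< {2 * cfg.window_s:.0f} s")
    tr = np.arange(0.0, t[-1], 1.0 / cfg.resample_hz)
    if cfg.interpolation == "cubic_spline":
        xr = interpolate.CubicSpline(t, x)(tr)
    else:
        xr = np.interp(tr, t, x)
    xr = xr - np.mean(xr)

    nperseg = int(round(cfg.window_s * cfg.resample_hz))
    noverlap = int(round(nperseg * cfg.overlap))
    f, psd = signal.welch(xr, fs=cfg.resample_hz, window=cfg.taper,
                          nperseg=nperseg, noverlap=noverlap,
                          detrend="constant")
    df = f[1] - f[0]

    def band(lo: float, hi: float) -> float:
        m = (f >= lo) & (f < hi)
        return float(np.sum(psd[m]) * df)

    vlf = band(0.0, cfg.vlf_hi)
    lf = band(cfg.vlf_hi, cfg.lf_hi)
    hf = band(cfg.lf_hi, cfg.hf_hi)
    tp = vlf + lf + hf
    denom = tp - vlf
    nlf = 100.0 * lf / denom if denom > 0 else float("nan")
    nhf = 100.0 * hf / denom if denom > 0 else float("nan")
    logs = log_panel({"tp": tp, "vlf": vlf, "lf": lf, "hf": hf})
    return HRVFreqDomain(
        tp_ms2=tp, vlf_ms2=vlf, lf_ms2=lf, hf_ms2=hf,
        log_tp=logs["tp"], log_vlf=logs["vlf"],
        log_lf=logs["lf"], log_hf=logs["hf"],
        nlf=nlf, nhf=nhf,
        lf_hf_ratio=lf / hf if hf > 0 else float("inf"),
    )


def log_panel(values: dict) -> dict:
    """Base-10 logarithm of a panel of positive power/interval quantities."""
    out = {}
    for k, v in values.items():
        if v <= 0:
            raise ValueError(f"log transform requires positive values; {k}={v}")
        out[k] = float(np.log10(v))
    return out
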
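"""Synthetic physiological signal generators with analytically known structure.

The generators provide ground truth for the downstream estimators: an
arterial-blood-pressure (ABP) waveform with a cardiac pulse, a Mayer-wave
oscillation near 0.1 Hz, slow drift and additive noise; a cerebral
blood-flow-velocity (CBFV) channel produced from ABP through a linear
system whose frequency response H(f) is available in closed form; and a
beat-interval (NN) series with oscillatory power placed in the LF
(0.04-0.15 Hz) and HF (0.15-0.40 Hz) bands plus injectable ectopic beats.

Because H(f) and the band amplitudes are known exactly, every transfer
function / spectral estimate computed downstream can be checked against an
analytic oracle instead of against patient recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .hrv import NNSeries
from .signals import UniformSignal


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class ABPSpec:
    """Recipe for a synthetic arterial-blood-pressure recording.

    The Mayer-wave component is the in-band (0.04-0.15 Hz) excitation that
    transfer function analysis relies on; the cardiac component sits far
    above the analysis band and mostly stresses the resampling stage.
    """

    duration_s: float = 600.0
    fs: float = 10.0
    mean_mmHg: float = 90.0
    cardiac_freq_hz: float = 1.1
    cardiac_amp_mmHg: float = 15.0
    mayer_freq_hz: float = 0.10
    mayer_amp_mmHg: float = 3.0
    drift_amp_mmHg: float = 1.5
    drift_freq_hz: float = 0.01
    noise_sd_mmHg: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        _require(self.duration_s > 0, "duration_s", "must be positive")
        _require(self.fs >= 4 * self.cardiac_freq_hz, "fs",
                 "must be at least 4x cardiac_freq_hz")
        for name in ("cardiac_amp_mmHg", "mayer_amp_mmHg", "drift_amp_mmHg",
                     "noise_sd_mmHg"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        _require(0.04 < self.mayer_freq_hz < 0.15, "mayer_freq_hz",
                 "must lie inside (0.04, 0.15) Hz")


@dataclass(frozen=True)
class AutoregFilterSpec:
    """Linear ABP->CBFV system with a closed-form frequency response.

    kinds
    -----
    ``identity``
        H(f) = dc_gain; CBFV is a scaled copy of ABP (no autoregulation
        dynamics, zero phase).
    ``pure_delay``
        H(f) = dc_gain * exp(-i 2 pi f delay_s); CBFV lags ABP, phase
        -360 f delay_s degrees.
    ``first_order_lead``
        H(f) = dc_gain * (1 + i 2 pi f T); CBFV leads ABP with phase
        arctan(2 pi f T) > 0, the signature of intact autoregulation
        (the vasculature counteracts slow pressure swings, advancing flow
        relative to pressure).

    ``noise_sd`` adds independent Gaussian noise on the output side (in
    output units) so magnitude-squared coherence below 1 can be dialled in.
    """

    kind: str = "first_order_lead"
    delay_s: float = 0.0
    lead_time_constant_s: float = 1.0
    dc_gain: float = 1.0
    noise_sd: float = 0.0
    noise_seed: int = 0

    _KINDS = ("identity", "pure_delay", "first_order_lead")

    def validate(self) -> None:
        _require(self.kind in self._KINDS, "kind",
                 f"must be one of {self._KINDS}")
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        if self.kind == "pure_delay":
            _require(self.delay_s >= 0, "delay_s", "must be non-negative")

    def frequency_response(self, f) -> np.ndarray:
        """Evaluate H(f) (complex) at frequencies ``f`` in Hz."""
        self.validate()
        f = np.asarray(f, dtype=float)
        if self.kind == "identity":
            return np.full(f.shape, self.dc_gain, dtype=complex)
        if self.kind == "pure_delay":
            return self.dc_gain * np.exp(-2j * np.pi * f * self.delay_s)
        # first_order_lead
        return self.dc_gain * (1.0 + 2j * np.pi * f * self.lead_time_constant_s)

    def phase_deg(self, f) -> np.ndarray:
        """Closed-form phase of H(f) in degrees (positive = output leads)."""
        return np.rad2deg(np.angle(self.frequency_response(f)))

    def gain_abs(self, f) -> np.ndarray:
        """Closed-form |H(f)|."""
        return np.abs(self.frequency_response(f))

    @staticmethod
    def lead_for_phase(target_phase_deg: float, at_freq_hz: float,
                       dc_gain: float = 1.0, **kw) -> "AutoregFilterSpec":
        """First-order-lead spec whose phase at ``at_freq_hz`` equals the target.

        Solves arctan(2 pi f T) = phase for the time constant T.
        """
        if not 0 < target_phase_deg < 90:
            raise ValueError("target phase must lie in (0, 90) degrees")
        T = math.tan(math.radians(target_phase_deg)) / (2 * math.pi * at_freq_hz)
        return AutoregFilterSpec(kind="first_order_lead",
                                 lead_time_constant_s=T, dc_gain=dc_gain, **kw)


@dataclass(frozen=True)
class NNSpec:
    """Recipe for a beat-interval (NN) series with known band structure.

    Two sinusoidal modulations of the heart period place power at
    ``lf_freq_hz`` (sympathetic/baroreflex band) and ``hf_freq_hz``
    (respiratory band); a sinusoid of amplitude A contributes power A^2/2,
    so the generated LF/HF power ratio is (lf_amp/hf_amp)^2.
    """

    n_beats: int = 700
    mean_nn_ms: float = 850.0
    lf_freq_hz: float = 0.10
    lf_amp_ms: float = 25.0
    hf_freq_hz: float = 0.25
    hf_amp_ms: float = 25.0
    noise_sd_ms: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_beats >= 2, "n_beats", "must be at least 2")
        _require(self.mean_nn_ms > 0, "mean_nn_ms", "must be positive")
        _require(0.04 <= self.lf_freq_hz < 0.15, "lf_freq_hz",
                 "must lie in [0.04, 0.15) Hz")
        _require(0.15 <= self.hf_freq_hz <= 0.40, "hf_freq_hz",
                 "must lie in [0.15, 0.40] Hz")
        for name in ("lf_amp_ms", "hf_amp_ms", "noise_sd_ms"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        # a crude positivity guard; generation re-checks the realised series
        _require(self.lf_amp_ms + self.hf_amp_ms + 5 * self.noise_sd_ms
                 < self.mean_nn_ms, "mean_nn_ms",
                 "amplitudes/noise too large for positive intervals")


def generate_abp(spec: ABPSpec) -> UniformSignal:
    """Generate a synthetic ABP recording per ``spec``.

    Deterministic for a fixed seed; with all amplitudes and noise zero the
    output is constant at ``mean_mmHg``.
    """
    spec.validate()
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(spec.seed)
    # random phases keep repeated subjects from being phase-locked copies
    ph = rng.uniform(0, 2 * np.pi, size=3)
    x = (spec.mean_mmHg
         + spec.cardiac_amp_mmHg * np.sin(2 * np.pi * spec.cardiac_freq_hz * t + ph[0])
         + spec.mayer_amp_mmHg * np.sin(2 * np.pi * spec.mayer_freq_hz * t + ph[1])
         + spec.drift_amp_mmHg * np.sin(2 * np.pi * spec.drift_freq_hz * t + ph[2])
         + rng.normal(0.0, spec.noise_sd_mmHg, size=n))
    return UniformSignal(x, spec.fs, name="abp", units="mmHg")


def apply_autoreg_filter(abp: UniformSignal, filt: AutoregFilterSpec) -> UniformSignal:
    """Pass an ABP signal through the closed-form linear system.

    The filter is applied in the frequency domain (circular convolution;
    the generated signals are long relative to the system memory so edge
    effects are negligible at the analysis band). Independent Gaussian
    output noise of SD ``filt.noise_sd`` is then added.
    """
    filt.validate()
    n = abp.n
    f = np.fft.rfftfreq(n, d=1.0 / abp.fs)
    H = filt.frequency_response(f)
    y = np.fft.irfft(np.fft.rfft(abp.data) * H, n=n)
    if filt.noise_sd > 0:
        rng = np.random.default_rng(filt.noise_seed)
        y = y + rng.normal(0.0, filt.noise_sd, size=n)
    return abp.with_data(y, name="cbfv", units="cm/s")


def generate_nn_series(spec: NNSpec) -> NNSeries:
    """Generate an NN-interval series with known LF/HF band amplitudes.

    The modulating sinusoids are evaluated on the cumulative beat-time axis
    so that their frequencies are true frequencies in Hz, matching the
    axis the spectral analysis resamples onto.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ph = rng.uniform(0, 2 * np.pi, size=2)
    # approximate beat times from the mean period; the modulation is small
    t = np.arange(spec.n_beats) * spec.mean_nn_ms / 1000.0
    nn = (spec.mean_nn_ms
          + spec.lf_amp_ms * np.sin(2 * np.pi * spec.lf_freq_hz * t + ph[0])
          + spec.hf_amp_ms * np.sin(2 * np.pi * spec.hf_freq_hz * t + ph[1])
          + rng.normal(0.0, spec.noise_sd_ms, size=spec.n_beats))
    if np.any(nn <= 0):
        raise ValueError("generated NN intervals not all positive; "
                         "reduce amplitudes or noise")
    return NNSeries(intervals_ms=nn)


def inject_ectopics(nn: NNSeries, fraction: float, seed: int) -> NNSeries:
    """Replace ``ceil(fraction * n)`` intervals by detectable ectopic values.

    Chosen intervals are shortened to 55% of their value (a premature beat),
    guaranteeing a deviation of at least 40% from the local median of an
    otherwise clean series. Ground-truth positions are recorded on the
    returned series as ``injected_positions``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    x = np.array(nn.intervals_ms, dtype=float)
    n = x.size
    k = math.ceil(fraction * n)
    if k == 0:
        return replace(nn, injected_positions=())
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(n, size=k, replace=False))
    x[pos] = 0.55 * x[pos]
    return replace(nn, intervals_ms=x, injected_positions=tuple(int(p) for p in pos))


# -- config plumbing ---------------------------------------------------------

_SPEC_TYPES = {"abp": ABPSpec, "autoreg_filter": AutoregFilterSpec, "nn": NNSpec}


def spec_from_dict(kind: str, d: dict):
    """Build a generator spec from a plain mapping (YAML/JSON block)."""
    try:
        cls = _SPEC_TYPES[kind]
    except KeyError:
        raise ValueError(f"unknown spec kind {kind!r}") from None
    return cls(**d)


def load_config(path) -> dict:
    """Load a YAML config whose top-level keys name spec kinds."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: spec_from_dict(k, v) for k, v in raw.items()}
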
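"""Uniformly sampled physiological signal container and plain-text I/O.

The container deliberately carries units and a channel name so that an
arterial-blood-pressure trace (mmHg) and a cerebral-blood-flow-velocity
trace (cm/s) cannot be confused downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class UniformSignal:
    """An evenly sampled time series.

    Parameters
    ----------
    data:
        Sample values, one per tick.
    fs:
        Sampling rate in Hz.
    name:
        Channel name, e.g. ``"abp"`` or ``"cbfv_left"``.
    units:
        Physical units of ``data``, e.g. ``"mmHg"`` or ``"cm/s"``.
    t0:
        Time of the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    name: str = "signal"
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 1:
            raise ValueError("data must be one-dimensional")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_data(self, data: np.ndarray, **changes) -> "UniformSignal":
        return replace(self, data=np.asarray(data, dtype=float), **changes)


def write_channel(path, sig: UniformSignal) -> None:
    """Write a single channel as two-column delimited text (time_s, value)."""
    df = pd.DataFrame({"time_s": sig.times, f"{sig.name}_{sig.units}".rstrip("_"): sig.data})
    df.to_csv(path, index=False)


def write_pair(path, abp: UniformSignal, cbfv: UniformSignal) -> None:
    """Write an ABP/CBFV pair as three-column text (time_s, abp_mmHg, cbfv_cms)."""
    if abp.n != cbfv.n or abp.fs != cbfv.fs:
        raise ValueError("paired channels must share length and sampling rate")
    df = pd.DataFrame(
        {"time_s": abp.times, "abp_mmHg": abp.data, "cbfv_cms": cbfv.data}
    )
    df.to_csv(path, index=False)


def read_pair(path) -> tuple[UniformSignal, UniformSignal]:
    """Read a three-column paired file written by :func:`write_pair`."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("paired file must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("paired file is not uniformly sampled")
    fs = 1.0 / dt[0]
    abp = UniformSignal(df["abp_mmHg"].to_numpy(), fs, name="abp", units="mmHg", t0=t[0])
    cbfv = UniformSignal(df["cbfv_cms"].to_numpy(), fs, name="cbfv", units="cm/s", t0=t[0])
    return abp, cbfv


def write_nn(path, intervals_ms: np.ndarray) -> None:
    """Write a beat-interval series, one value (ms) per line."""
    np.savetxt(path, np.asarray(intervals_ms, dtype=float), fmt="%.6f")


def read_nn(path) -> np.ndarray:
    """Read a one-interval-per-line beat series (ms)."""
    return np.atleast_1d(np.loadtxt(path, dtype=float))
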
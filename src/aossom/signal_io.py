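"""Sensor-array recordings: data model, text dialect, and preprocessing.

A recording is the raw output of a 10-sensor metal-oxide (MOS) gas-sensor
array sampling the headspace gas of one soil sample: ten voltage time series
read across a load resistor ``RL`` in a voltage divider driven at ``Vc``,
one series per sensor, each sensor held at its own constant heater voltage
so the array spans ten working temperatures.

The on-disk dialect ("AOS-TS v1") is plain delimited text: ``#`` comment
lines carrying ``key=value`` metadata, then a ``time_s,S1,...,S10`` header
row, then one row per time point.  Preprocessing applies a one-dimensional
median filter per channel and truncates to the first acquisition window
(5 min at 10 Hz, i.e. 3000 samples, by default).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter as _nd_median_filter

from .exceptions import LengthError, ParameterError, ParseError

__all__ = [
    "N_SENSORS",
    "DEFAULT_HEATER_VOLTAGES",
    "SensorRecording",
    "read_recording",
    "write_recording",
    "median_filter",
    "preprocess",
]

N_SENSORS = 10

#: Heater voltages S1..S10: 1.25 V to 3.50 V in 0.25 V steps.
DEFAULT_HEATER_VOLTAGES = tuple(np.round(np.arange(1.25, 3.50 + 1e-9, 0.25), 2))

#: Minimum channel length so the transient value at t = 20 s exists
#: (sample 201 under the t = (i-1)*dt convention at dt = 0.1 s).
MIN_SAMPLES = 201


@dataclass
class SensorRecording:
    """One soil sample's 10-channel voltage time series plus metadata.

    Sample ``i`` (1-based) is taken at ``t = (i - 1) * dt``, so the first
    sample sits at t = 0 and "the 20th second" lands exactly on a grid
    point.

    Parameters
    ----------
    sample_id : str
        Identifier of the soil sample.
    channels : ndarray, shape (10, N)
        Output voltages (V) for sensors S1..S10, equal length per channel.
    dt : float
        Sampling interval in seconds (0.1 s = 10 Hz by default).
    heater_voltages : tuple of 10 floats
        Constant heater voltage per sensor (V), ordered S1..S10.
    vc : float
        Circuit (divider supply) voltage in volts.
    rl : float
        Load resistance in ohms.
    som_reference : float or None
        Reference soil-organic-matter content (g/kg), when known.
    """

    sample_id: str
    channels: np.ndarray
    dt: float = 0.1
    heater_voltages: tuple = DEFAULT_HEATER_VOLTAGES
    vc: float = 5.0
    rl: float = 10_000.0
    som_reference: float | None = None

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != N_SENSORS:
            raise ParameterError(
                f"expected {N_SENSORS} channels, got shape {self.channels.shape}"
            )
        if self.channels.shape[1] < MIN_SAMPLES:
            raise LengthError(
                f"channels must have at least {MIN_SAMPLES} samples "
                f"(got {self.channels.shape[1]})"
            )
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.vc <= 0 or self.rl <= 0:
            raise ParameterError("vc and rl must be positive")
        if len(self.heater_voltages) != N_SENSORS:
            raise ParameterError("heater_voltages must have 10 entries")
        self.heater_voltages = tuple(float(v) for v in self.heater_voltages)
        if not np.isfinite(self.channels).all():
            raise ParameterError("channel voltages must be finite")
        if self.channels.min() < 0 or self.channels.max() > self.vc + 1e-9:
            raise ParameterError(
                "channel voltages must lie within [0, Vc] "
                f"(Vc = {self.vc}, observed range "
                f"[{self.channels.min():.4g}, {self.channels.max():.4g}])"
            )

    @property
    def n_samples(self) -> int:
        """Number of time points per channel."""
        return self.channels.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Time grid t_i = (i - 1) * dt, in seconds."""
        return np.arange(self.n_samples) * self.dt

    def __eq__(self, other):
        if not isinstance(other, SensorRecording):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.channels, other.channels)
            and self.dt == other.dt
            and self.heater_voltages == other.heater_voltages
            and self.vc == other.vc
            and self.rl == other.rl
            and self.som_reference == other.som_reference
        )


def _parse_metadata(lines):
    meta = {}
    for lineno, line in lines:
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        meta[key.strip()] = (value.strip(), lineno)
    return meta


def read_recording(path) -> SensorRecording:
    """Read an AOS-TS v1 text file into a :class:`SensorRecording`.

    The delimiter (comma or tab) is auto-detected from the column header
    row.  Channel order follows the column order S1..S10.

    Raises
    ------
    ParseError
        On malformed header, wrong channel count, non-monotone time column,
        or a non-numeric cell; the message names the offending line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.read().splitlines()

    comment_lines = []
    data_start = None
    for i, line in enumerate(raw_lines):
        if line.startswith("#"):
            comment_lines.append((i + 1, line))
        elif line.strip():
            data_start = i
            break
    if data_start is None:
        raise ParseError("file contains no data rows")

    meta = _parse_metadata(comment_lines)
    header = raw_lines[data_start]
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    columns = [c.strip() for c in header.split(sep)]
    if columns[0] != "time_s":
        raise ParseError(
            f"expected first column 'time_s', got {columns[0]!r}",
            line=data_start + 1,
        )
    n_channels = len(columns) - 1
    if n_channels != N_SENSORS:
        raise ParseError(
            f"expected {N_SENSORS} channels, got {n_channels}",
            line=data_start + 1,
        )

    body = "\n".join(raw_lines[data_start:])
    try:
        frame = pd.read_csv(io.StringIO(body), sep=sep)
        values = frame.to_numpy(dtype=float)
    except (ValueError, TypeError):
        # locate the offending cell for a line-numbered message
        for j, line in enumerate(raw_lines[data_start + 1:], start=data_start + 2):
            for cell in line.split(sep):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(f"non-numeric cell {cell!r}", line=j) from None
        raise ParseError("malformed data table", line=data_start + 1) from None

    time = values[:, 0]
    if np.any(np.diff(time) <= 0):
        bad = int(np.argmax(np.diff(time) <= 0)) + 1
        raise ParseError(
            "time column is not strictly increasing",
            line=data_start + 1 + bad + 1,
        )

    def _get(key, default=None, cast=float):
        if key in meta:
            value, lineno = meta[key]
            try:
                return cast(value)
            except ValueError:
                raise ParseError(f"bad metadata value for {key}: {value!r}",
                                 line=lineno) from None
        return default

    dt = _get("dt", default=float(np.median(np.diff(time))) if len(time) > 1 else 0.1)
    vh_default = ",".join(f"{v:.2f}" for v in DEFAULT_HEATER_VOLTAGES)
    vh_raw = _get("vh", default=vh_default, cast=str)
    try:
        heater = tuple(float(v) for v in vh_raw.split(","))
    except ValueError:
        raise ParseError(f"bad heater voltage list: {vh_raw!r}") from None

    return SensorRecording(
        sample_id=_get("sample_id", default="unknown", cast=str),
        channels=values[:, 1:].T,
        dt=dt,
        heater_voltages=heater,
        vc=_get("vc", default=5.0),
        rl=_get("rl", default=10_000.0),
        som_reference=_get("som_g_per_kg", default=None),
    )


def write_recording(recording: SensorRecording, path) -> None:
    """Write a recording as AOS-TS v1 comma-delimited text.

    Voltages are written with 8 significant digits, so a read/write
    round trip preserves the data to at least 6 significant digits.
    """
    if not isinstance(recording, SensorRecording):
        raise ParameterError("expected a SensorRecording")
    lines = [
        f"# sample_id={recording.sample_id}",
        f"# dt={recording.dt!r}",
        f"# vc={recording.vc!r}",
        f"# rl={recording.rl!r}",
        "# vh=" + ",".join(f"{v:.2f}" for v in recording.heater_voltages),
    ]
    if recording.som_reference is not None:
        lines.append(f"# som_g_per_kg={recording.som_reference!r}")
    lines.append("time_s," + ",".join(f"S{k}" for k in range(1, N_SENSORS + 1)))
    time = recording.time
    for i in range(recording.n_samples):
        row = ",".join(f"{v:.8g}" for v in recording.channels[:, i])
        lines.append(f"{time[i]:.8g},{row}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def median_filter(series, window: int = 5) -> np.ndarray:
    """One-dimensional running median with reflected edges.

    Each point is replaced by the median of its centred ``window``-sample
    neighbourhood; the series is reflected at both ends so the output has
    the same length as the input.

    Parameters
    ----------
    series : array-like
        Voltage series.
    window : int
        Odd, positive window length, at most ``len(series)``.
    """
    series = np.asarray(series, dtype=float)
    if window <= 0 or window % 2 == 0:
        raise ParameterError(f"window must be odd and positive, got {window}")
    if series.ndim != 1 or series.size == 0:
        raise LengthError("series must be a non-empty 1-D array")
    if window > series.size:
        raise ParameterError(
            f"window ({window}) exceeds series length ({series.size})"
        )
    return _nd_median_filter(series, size=window, mode="reflect")


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing options: filter window (samples) and window duration (s)."""

    filter_window: int = 5
    duration: float = 300.0


def preprocess(recording: SensorRecording,
               config: PreprocessConfig | None = None) -> SensorRecording:
    """Median-filter every channel, then truncate to the acquisition window.

    The retained window is ``round(duration / dt)`` samples (3000 at the
    10 Hz / 5 min defaults).  Recordings longer than the window are
    truncated; shorter ones raise :class:`LengthError`.
    """
    config = config or PreprocessConfig()
    n_keep = int(round(config.duration / recording.dt))
    if recording.n_samples < n_keep:
        raise LengthError(
            f"recording has {recording.n_samples} samples but the "
            f"{config.duration} s window needs {n_keep}"
        )
    filtered = np.stack([
        median_filter(ch, config.filter_window) for ch in recording.channels
    ])
    return replace(recording, channels=filtered[:, :n_keep])
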
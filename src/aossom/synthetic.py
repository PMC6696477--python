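"""Synthetic sensor-array recordings with the structure the method assumes.

No public dataset of raw electronic-nose soil recordings exists, so the
pipeline is exercised on simulated arrays built from the same physical
picture the hardware realises:

* soil organic matter (SOM, g/kg) drives an effective volatile-organic-
  compound concentration in the sealed headspace, monotonically, via a
  power law ``c = kappa * SOM**gamma``;
* each metal-oxide sensor's resistance declines nonlinearly with gas
  concentration and relaxes first-order in time,
  ``Rs(t) = R0 * (1 + s*c*(1 - exp(-t/tau)))**(-p)``;
* the measured signal is the voltage-divider readout
  ``Vout = RL / (RL + Rs) * Vc`` plus additive Gaussian noise, clipped to
  the supply rails.

Array diversity (achieved in hardware by running each sensor at its own
heater voltage) is emulated by distinct sensitivity, decline exponent and
rise time per sensor.  SOM values are drawn from a truncated normal whose
defaults match the reference-survey statistics (mean 23.0, SD 7.4 g/kg,
bounds 12-49 g/kg).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ParameterError
from .signal_io import DEFAULT_HEATER_VOLTAGES, N_SENSORS, SensorRecording

__all__ = [
    "CARBON_TO_SOM",
    "SensorParams",
    "SimulatorConfig",
    "organic_carbon_to_som",
    "sample_som",
    "output_voltage",
    "sensor_response",
    "simulate_dataset",
    "default_sensor_params",
]

#: Conversion constant from soil organic carbon to soil organic matter.
CARBON_TO_SOM = 1.724


def organic_carbon_to_som(organic_carbon: float) -> float:
    """Convert organic carbon (g/kg) to soil organic matter (g/kg).

    SOM is organic carbon consumption multiplied by the constant 1.724
    (the conventional Van Bemmelen factor used with dichromate titration).
    """
    oc = np.asarray(organic_carbon, dtype=float)
    if np.any(oc < 0):
        raise ParameterError("organic carbon must be non-negative")
    result = oc * CARBON_TO_SOM
    return float(result) if np.isscalar(organic_carbon) else result


@dataclass(frozen=True)
class SensorParams:
    """Response parameters of one simulated MOS sensor.

    Attributes
    ----------
    baseline_resistance : float
        Clean-air sensor resistance R0 (ohm), > 0.
    sensitivity : float
        Gain ``s`` coupling effective gas concentration to the resistance
        decline, >= 0 (an insensitive sensor has s = 0).
    decline_exponent : float
        Power-law exponent ``p`` of the resistance decline, > 0.
    rise_time : float
        First-order time constant tau (s) of the transient, > 0.
    noise_sd : float
        Standard deviation of the additive readout noise (V), >= 0.
    """

    baseline_resistance: float
    sensitivity: float
    decline_exponent: float
    rise_time: float
    noise_sd: float = 0.005

    def __post_init__(self):
        if self.baseline_resistance <= 0:
            raise ParameterError("baseline_resistance must be > 0")
        if self.sensitivity < 0:
            raise ParameterError("sensitivity must be >= 0")
        if self.decline_exponent <= 0:
            raise ParameterError("decline_exponent must be > 0")
        if self.rise_time <= 0:
            raise ParameterError("rise_time must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    def fingerprint(self) -> int:
        """Stable 32-bit hash of the parameter values.

        Used to derive a per-sensor noise stream that follows the sensor
        (so permuting the array permutes channels identically).
        """
        payload = repr((self.baseline_resistance, self.sensitivity,
                        self.decline_exponent, self.rise_time,
                        self.noise_sd)).encode()
        return int.from_bytes(hashlib.blake2b(payload, digest_size=4).digest(),
                              "big")


def default_sensor_params(noise_sd: float = 0.005) -> list[SensorParams]:
    """Ten-sensor array emulating the heater-voltage ladder.

    Sensitivity rises and the transient shortens with working temperature;
    baseline resistance falls, as is typical of heated MOS elements.
    """
    out = []
    for k in range(N_SENSORS):
        frac = k / (N_SENSORS - 1)
        out.append(SensorParams(
            baseline_resistance=30_000.0 * (1.0 - 0.6 * frac),
            sensitivity=0.6 + 1.8 * frac,
            decline_exponent=0.6 + 0.9 * frac,
            rise_time=120.0 - 100.0 * frac,
            noise_sd=noise_sd,
        ))
    return out


@dataclass
class SimulatorConfig:
    """Full configuration of a simulated acquisition campaign.

    Defaults follow the reference survey: 102 samples, SOM truncated
    normal with mean 23.0 and SD 7.4 g/kg on [12, 49] g/kg, 10 sensors,
    10 Hz sampling for 5 minutes.
    """

    n_samples: int = 102
    som_mean: float = 23.0
    som_sd: float = 7.4
    som_min: float = 12.0
    som_max: float = 49.0
    concentration_gain: float = 0.1
    concentration_exponent: float = 0.8
    sensors: list[SensorParams] = field(default_factory=default_sensor_params)
    vc: float = 5.0
    rl: float = 10_000.0
    dt: float = 0.1
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        if not self.som_min < self.som_max:
            raise ParameterError("require som_min < som_max")
        if len(self.sensors) != N_SENSORS:
            raise ParameterError(f"exactly {N_SENSORS} SensorParams required")
        if self.som_sd <= 0:
            raise ParameterError("som_sd must be > 0")
        if self.concentration_gain <= 0 or self.concentration_exponent <= 0:
            raise ParameterError("concentration law parameters must be > 0")

    @property
    def n_points(self) -> int:
        return int(round(self.duration / self.dt))

    def concentration(self, som) -> np.ndarray:
        """Effective VOC concentration c = kappa * SOM**gamma."""
        return self.concentration_gain * np.asarray(som, float) ** self.concentration_exponent


def sample_som(n: int, config: SimulatorConfig, seed: int) -> np.ndarray:
    """Draw ``n`` SOM values (g/kg) from the configured truncated normal."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    a = (config.som_min - config.som_mean) / config.som_sd
    b = (config.som_max - config.som_mean) / config.som_sd
    if not a < b:
        raise ParameterError("empty truncation interval")
    rng = np.random.default_rng(seed)
    return stats.truncnorm.rvs(a, b, loc=config.som_mean, scale=config.som_sd,
                               size=n, random_state=rng)


def output_voltage(Rs, RL: float, Vc: float):
    """Voltage-divider readout ``Vout = RL / (RL + Rs) * Vc``.

    Strictly decreasing in the sensor resistance ``Rs`` and bounded in
    (0, Vc] for Rs >= 0.
    """
    if RL <= 0:
        raise ParameterError("load resistance RL must be > 0")
    Rs = np.asarray(Rs, dtype=float)
    if np.any(Rs < 0):
        raise ParameterError("sensor resistance must be >= 0")
    out = RL / (RL + Rs) * Vc
    return float(out) if out.ndim == 0 else out


def _clean_response(som: float, params: SensorParams,
                    config: SimulatorConfig) -> np.ndarray:
    t = np.arange(config.n_points) * config.dt
    c = float(config.concentration(som))
    rs = params.baseline_resistance * (
        1.0 + params.sensitivity * c * (1.0 - np.exp(-t / params.rise_time))
    ) ** (-params.decline_exponent)
    return output_voltage(rs, config.rl, config.vc)


def sensor_response(som: float, params: SensorParams,
                    config: SimulatorConfig, seed: int) -> np.ndarray:
    """Simulate one sensor's voltage series for a sample of given SOM.

    The clean trajectory is the divider readout of the declining
    resistance; zero-mean Gaussian noise of ``params.noise_sd`` volts is
    added and the result clipped to [0, Vc].
    """
    if not (config.som_min <= som <= config.som_max):
        raise ParameterError(
            f"som {som} outside configured bounds "
            f"[{config.som_min}, {config.som_max}]"
        )
    clean = _clean_response(som, params, config)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, params.noise_sd, size=clean.size)
    return np.clip(clean, 0.0, config.vc)


def simulate_dataset(config: SimulatorConfig):
    """Simulate a full campaign: recordings plus true SOM labels.

    Returns
    -------
    recordings : list of SensorRecording
        ``config.n_samples`` recordings of 10 channels each, sample ids
        ``sim001``, ``sim002``, ...
    som : ndarray
        True SOM (g/kg) per sample, also stored on each recording.

    Notes
    -----
    Reproducibility: SOM draws use a sub-seed spawned from the master
    seed; each channel's noise stream is seeded by (master seed, sample
    index, sensor-parameter fingerprint), so reordering the sensor list
    permutes channels without changing their content.
    """
    ss = np.random.SeedSequence(config.seed)
    som_seed = ss.spawn(1)[0].generate_state(1)[0] % (2**31)
    som = sample_som(config.n_samples, config, int(som_seed))

    recordings = []
    width = max(3, len(str(config.n_samples)))
    for j in range(config.n_samples):
        channels = []
        for params in config.sensors:
            chan_seed = int(np.random.SeedSequence(
                entropy=config.seed,
                spawn_key=(j + 1, params.fingerprint()),
            ).generate_state(1)[0] % (2**31))
            channels.append(sensor_response(som[j], params, config, chan_seed))
        recordings.append(SensorRecording(
            sample_id=f"sim{j + 1:0{width}d}",
            channels=np.stack(channels),
            dt=config.dt,
            heater_voltages=DEFAULT_HEATER_VOLTAGES,
            vc=config.vc,
            rl=config.rl,
            som_reference=float(som[j]),
        ))
    return recordings, som
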
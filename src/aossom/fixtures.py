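"""Packaged reference data from the SOM survey that motivated the method.

Four small plain-text resources ship with the package:

* ``som_reference_survey.csv`` — the 102 dichromate-determined SOM
  contents (g/kg) of the development survey, with their
  training/validation assignment (71 / 31);
* ``heater_voltages.csv`` — the heater-voltage ladder of the 10-sensor
  array (1.25-3.50 V in 0.25 V steps) and measured working temperatures;
* ``bpnn_hidden_selection.csv`` — the published hidden-size selection
  grid (min/max/mean training R^2 and RMSE per candidate h);
* ``published_performance.csv`` — the published validation-set
  performance indices of the three calibrators (display/comparison
  only; the underlying raw sensor recordings were never released, so
  these numbers are not recomputable).

Loading the reference table re-derives its summary statistics and
checks them against the published values, failing loudly on drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import FixtureIntegrityError, LengthError

__all__ = [
    "ReferenceTable", "load_reference_table", "summarize",
    "load_heater_table", "load_bpnn_selection_table",
    "load_published_performance",
]

#: Published per-set summaries (max, min, mean, SD, CV%) of the survey.
_PUBLISHED_SUMMARY = {
    "training": (43.85, 12.37, 22.98, 7.27, 31.64),
    "validation": (48.79, 12.19, 23.49, 7.73, 32.90),
}
_EXPECTED_COUNTS = {"training": 71, "validation": 31}
#: Half a unit of the last printed decimal.
_TOL = 0.005


def _read(name: str) -> pd.DataFrame:
    with resources.files("aossom.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def summarize(values):
    """(max, min, mean, sd, cv%) of a value list; sd uses the n-1 divisor."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise LengthError("need at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return (float(values.max()), float(values.min()), mean, sd,
            100.0 * sd / mean)


@dataclass
class ReferenceTable:
    """The 102 reference SOM values with set labels and published summaries."""

    frame: pd.DataFrame
    published_summary: dict

    def values(self, subset: str | None = None) -> np.ndarray:
        """SOM values (g/kg), optionally one subset ("training"/"validation")."""
        frame = self.frame
        if subset is not None:
            frame = frame[frame["set"] == subset]
            if frame.empty:
                raise KeyError(f"unknown subset {subset!r}")
        return frame["som_g_per_kg"].to_numpy(dtype=float)

    def summary(self, subset: str):
        """Recomputed (max, min, mean, sd, cv%) for a subset."""
        return summarize(self.values(subset))


def load_reference_table() -> ReferenceTable:
    """Load and integrity-check the packaged 102-sample reference table.

    Raises
    ------
    FixtureIntegrityError
        If set counts or any recomputed summary cell disagree with the
        published values beyond half a unit of the last printed decimal.
    """
    frame = _read("som_reference_survey.csv")
    for subset, expected_n in _EXPECTED_COUNTS.items():
        values = frame.loc[frame["set"] == subset, "som_g_per_kg"]
        if len(values) != expected_n:
            raise FixtureIntegrityError(
                f"{subset} set has {len(values)} rows, expected {expected_n}"
            )
        recomputed = summarize(values.to_numpy(dtype=float))
        for got, want in zip(recomputed, _PUBLISHED_SUMMARY[subset]):
            if abs(got - want) > _TOL + 1e-12:
                raise FixtureIntegrityError(
                    f"{subset} summary drift: recomputed {recomputed}, "
                    f"published {_PUBLISHED_SUMMARY[subset]}"
                )
    return ReferenceTable(frame=frame,
                          published_summary=dict(_PUBLISHED_SUMMARY))


def load_heater_table() -> pd.DataFrame:
    """Heater voltage and working temperature per sensor, S1..S10."""
    return _read("heater_voltages.csv")


def load_bpnn_selection_table() -> pd.DataFrame:
    """Published hidden-size selection grid (candidates h = 6..16)."""
    return _read("bpnn_hidden_selection.csv")


def load_published_performance() -> pd.DataFrame:
    """Published validation performance of the three calibrators.

    For display and comparison only: the raw recordings behind these
    numbers were never released, so they cannot be recomputed.
    """
    return _read("published_performance.csv")
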
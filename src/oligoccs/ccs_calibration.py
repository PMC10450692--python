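"""Travelling-wave ion-mobility CCS calibration.

TWIMS drift times carry no first-principles relation to collision cross
section; they are calibrated empirically against reference ions of known CCS.
The standard protocol is implemented here:

1. correct each drift time for the instrument transfer delay (EDC term),
   ``td' = td - c * sqrt(m/z) / 1000``;
2. normalise each reference CCS by charge and reduced mass,
   ``ccs' = ccs / (z * sqrt(1/mu))`` with ``mu = m * M_gas / (m + M_gas)``;
3. fit the power law ``ccs' = A * td'^B`` by ordinary least squares in
   log-log space.

The fitted model maps any (drift time, m/z, z) to a CCS and is exactly
invertible, which the synthetic-data generator uses to plant drift times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Average proton mass in Da, used to strip charge adducts from m/z.
PROTON_MASS = 1.00728
#: Nitrogen drift-gas mass in Da (Synapt default buffer gas).
N2_MASS = 28.0134
#: Helium drift-gas mass in Da.
HE_MASS = 4.0026
#: Default enhanced-duty-cycle (EDC) delay coefficient.
DEFAULT_EDC_C = 1.41

CALIBRANT_COLUMNS = ["species", "charge", "mass_da", "ccs_a2", "drift_time_ms"]


@dataclass(frozen=True)
class CalibrantRecord:
    """One reference ion: species label, charge, mass, literature CCS, drift time."""

    species_name: str
    charge: int
    mass: float          # Da
    reference_ccs: float  # A^2
    drift_time: float     # ms

    def __post_init__(self) -> None:
        if self.charge <= 0:
            raise ValueError(f"charge must be positive, got {self.charge}")
        for name in ("mass", "reference_ccs", "drift_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class CalibrationModel:
    """Fitted power-law drift-time -> CCS mapping.

    ``ccs = A * z * sqrt(1/mu(m)) * td'^B`` with the EDC-corrected drift time
    ``td'`` and reduced mass ``mu(m) = m * M_gas / (m + M_gas)``.
    """

    power_coefficient_a: float
    exponent_b: float
    edc_coefficient_c: float = DEFAULT_EDC_C
    drift_gas_mass: float = N2_MASS
    fit_residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.exponent_b <= 0:
            raise ValueError("exponent_b must be positive")
        if self.drift_gas_mass <= 0:
            raise ValueError("drift_gas_mass must be positive")
        self.fit_residuals = np.asarray(self.fit_residuals, dtype=float)
        if not np.all(np.isfinite(self.fit_residuals)):
            raise ValueError("fit_residuals must be finite")

    def reduced_mass(self, mass: float) -> float:
        """mu(m) = m * M_gas / (m + M_gas), in Da."""
        return reduced_mass(mass, self.drift_gas_mass)

    def save(self, path: str | Path) -> None:
        """Serialize to a flat key-value text file."""
        lines = [
            f"power_coefficient_a\t{float(self.power_coefficient_a)!r}",
            f"exponent_b\t{float(self.exponent_b)!r}",
            f"edc_coefficient_c\t{float(self.edc_coefficient_c)!r}",
            f"drift_gas_mass\t{float(self.drift_gas_mass)!r}",
            "fit_residuals\t" + ",".join(repr(float(r)) for r in self.fit_residuals),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("\t")
            kv[key] = value
        residuals = np.array(
            [float(x) for x in kv.get("fit_residuals", "").split(",") if x],
            dtype=float,
        )
        return cls(
            power_coefficient_a=float(kv["power_coefficient_a"]),
            exponent_b=float(kv["exponent_b"]),
            edc_coefficient_c=float(kv["edc_coefficient_c"]),
            drift_gas_mass=float(kv["drift_gas_mass"]),
            fit_residuals=residuals,
        )


def reduced_mass(mass: float, drift_gas_mass: float = N2_MASS) -> float:
    """Reduced mass of the ion/drift-gas pair in Da."""
    if mass <= 0 or drift_gas_mass <= 0:
        raise ValueError("masses must be positive")
    return mass * drift_gas_mass / (mass + drift_gas_mass)


def corrected_drift_time(drift_time, mz, edc_coefficient_c: float = DEFAULT_EDC_C):
    """EDC-corrected drift time ``td - c * sqrt(m/z) / 1000`` in ms.

    Raises if the correction exceeds the measured drift time, which signals
    an EDC coefficient inconsistent with the data.
    """
    drift_time = np.asarray(drift_time, dtype=float)
    mz = np.asarray(mz, dtype=float)
    if np.any(drift_time <= 0) or np.any(mz <= 0):
        raise ValueError("drift_time and mz must be positive")
    corrected = drift_time - edc_coefficient_c * np.sqrt(mz) / 1000.0
    if np.any(corrected <= 0):
        raise ValueError(
            "EDC-corrected drift time is non-positive; "
            "edc_coefficient_c is inconsistent with the data"
        )
    return corrected if corrected.ndim else float(corrected)


def corrected_reference_ccs(
    reference_ccs, charge, mass, drift_gas_mass: float = N2_MASS
):
    """Charge/reduced-mass-normalised CCS: ``ccs / (z * sqrt(1/mu))``."""
    reference_ccs = np.asarray(reference_ccs, dtype=float)
    charge = np.asarray(charge, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if np.any(charge <= 0):
        raise ValueError("charge must be positive")
    if np.any(reference_ccs <= 0) or np.any(mass <= 0) or drift_gas_mass <= 0:
        raise ValueError("reference_ccs, mass and drift_gas_mass must be positive")
    mu = mass * drift_gas_mass / (mass + drift_gas_mass)
    out = reference_ccs / (charge * np.sqrt(1.0 / mu))
    return out if out.ndim else float(out)


def fit_calibration(
    calibrants: Sequence[CalibrantRecord],
    edc_coefficient_c: float = DEFAULT_EDC_C,
    drift_gas_mass: float = N2_MASS,
) -> CalibrationModel:
    """Fit (A, B) by OLS on ln(corrected CCS) vs ln(corrected drift time).

    Requires at least two calibrants with distinct corrected drift times.
    ``fit_residuals`` holds each calibrant's relative CCS error under the
    fitted model; with exactly two points the fit is exact.
    """
    if len(calibrants) < 2:
        raise ValueError("need at least 2 calibrant records")
    mz = np.array([c.mass / c.charge + PROTON_MASS for c in calibrants])
    td = np.array([c.drift_time for c in calibrants])
    tdc = corrected_drift_time(td, mz, edc_coefficient_c)
    if np.unique(np.round(tdc, 12)).size < 2:
        raise ValueError("calibrants have coincident corrected drift times")
    ccs_corr = corrected_reference_ccs(
        np.array([c.reference_ccs for c in calibrants]),
        np.array([c.charge for c in calibrants]),
        np.array([c.mass for c in calibrants]),
        drift_gas_mass,
    )
    slope, intercept = np.polyfit(np.log(tdc), np.log(ccs_corr), 1)
    model = CalibrationModel(
        power_coefficient_a=float(np.exp(intercept)),
        exponent_b=float(slope),
        edc_coefficient_c=edc_coefficient_c,
        drift_gas_mass=drift_gas_mass,
    )
    predicted = np.array(
        [
            apply_calibration(model, c.drift_time, c.mass / c.charge + PROTON_MASS, c.charge)
            for c in calibrants
        ]
    )
    model.fit_residuals = (predicted - np.array([c.reference_ccs for c in calibrants])) / np.array(
        [c.reference_ccs for c in calibrants]
    )
    return model


def _ion_mass(mz, charge) -> np.ndarray:
    return np.asarray(charge, dtype=float) * (np.asarray(mz, dtype=float) - PROTON_MASS)


def apply_calibration(model: CalibrationModel, drift_time, mz, charge):
    """CCS (A^2) for a measured ion under the fitted model."""
    charge = np.asarray(charge)
    if np.any(charge <= 0):
        raise ValueError("charge must be positive")
    mass = _ion_mass(mz, charge)
    mu = mass * model.drift_gas_mass / (mass + model.drift_gas_mass)
    tdc = corrected_drift_time(drift_time, mz, model.edc_coefficient_c)
    out = (
        model.power_coefficient_a
        * charge
        * np.sqrt(1.0 / mu)
        * np.power(tdc, model.exponent_b)
    )
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def invert_calibration(model: CalibrationModel, ccs, mz, charge):
    """Drift time (ms) that the model would map to the given CCS.

    Exact inverse of :func:`apply_calibration`, including the EDC term.
    """
    ccs = np.asarray(ccs, dtype=float)
    charge = np.asarray(charge)
    if np.any(ccs <= 0):
        raise ValueError("ccs must be positive")
    if np.any(charge <= 0):
        raise ValueError("charge must be positive")
    mass = _ion_mass(mz, charge)
    mu = mass * model.drift_gas_mass / (mass + model.drift_gas_mass)
    ccs_corr = ccs / (charge * np.sqrt(1.0 / mu))
    tdc = np.power(ccs_corr / model.power_coefficient_a, 1.0 / model.exponent_b)
    out = tdc + model.edc_coefficient_c * np.sqrt(np.asarray(mz, dtype=float)) / 1000.0
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def read_calibrant_table(path: str | Path) -> list[CalibrantRecord]:
    """Read a calibrant table (CSV/TSV, header species,charge,mass_da,ccs_a2,drift_time_ms)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision='round_trip')
    missing = set(CALIBRANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibrant table missing columns: {sorted(missing)}")
    return [
        CalibrantRecord(
            species_name=str(r.species),
            charge=int(r.charge),
            mass=float(r.mass_da),
            reference_ccs=float(r.ccs_a2),
            drift_time=float(r.drift_time_ms),
        )
        for r in df.itertuples()
    ]


def write_calibrant_table(records: Iterable[CalibrantRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "species": r.species_name,
                "charge": r.charge,
                "mass_da": r.mass,
                "ccs_a2": r.reference_ccs,
                "drift_time_ms": r.drift_time,
            }
            for r in records
        ],
        columns=CALIBRANT_COLUMNS,
    )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
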
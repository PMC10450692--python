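"""Synthetic nanoESI-IM-MS oligomer ensembles with known ground truth.

No public raw data accompany native MS oligomer studies of this kind, so
every pipeline input is generated here with planted parameters that the
analysis must recover: a calibrant table drawn from a known power law,
variant peak lists with a geometric oligomer-abundance decay, a
variant-dependent boost of large states, isotropic and/or linear CCS growth
families with overlapping n/z species, and Gaussian/lognormal measurement
noise. Ground-truth tables always accompany the generated peaks, so every
feature is traceable to one planted (n, z, family).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ccs_calibration import (
    PROTON_MASS,
    CalibrantRecord,
    CalibrationModel,
    invert_calibration,
)
from .growth_families import isotropic_ccs
from .oligomer_assignment import SpectralFeature, oligomer_mz

#: Aβ(1-40) average mass (Da), the monomer the defaults are sized to.
DEFAULT_MONOMER_MASS = 4329.86


@dataclass(frozen=True)
class EnsembleConfig:
    """Stated world for one variant's oligomer ensemble.

    Abundances decay geometrically with state (``abundance_decay`` per
    state), emulating spectra with no preferred oligomeric state and a
    gradual intensity decrease; ``large_state_boost`` multiplies states
    n >= ``boost_threshold`` (the aggregation-prone-variant signature).
    Charge states per n follow ``round(z_monomer * n^(2/3)) +/- 1`` with
    triangular weights, mimicking the observed charge progression. CCS
    values follow the chosen growth mode; drift times come from inverting
    the calibration. Monomer CCS anchors default to round numbers
    (600/700 A^2) rather than any literature value.
    """

    monomer_mass: float = DEFAULT_MONOMER_MASS
    max_state: int = 10
    abundance_decay: float = 0.6
    large_state_boost: float = 1.0
    boost_threshold: int = 8
    z_monomer: int = 3
    monomer_ccs_z2: float = 600.0
    monomer_ccs_z3: float = 700.0
    growth_mode: str = "isotropic"  # isotropic | linear_above_4 | mixture
    linear_slope_factor: float = 0.45  # L slope as a fraction of the I3 anchor CCS
    mixture_weights: dict[int, tuple[float, float]] | None = None  # n -> (w_iso, w_lin)
    linear_charge_shift: int = 3  # extra charge carried by elongated (L) species
    noise_mz_ppm: float = 20.0
    noise_drift_rel: float = 0.01
    noise_intensity_rel: float = 0.05
    base_intensity: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.abundance_decay <= 1.0:
            raise ValueError("abundance_decay must be in (0, 1]")
        if self.large_state_boost < 1.0:
            raise ValueError("large_state_boost must be >= 1")
        if min(self.noise_mz_ppm, self.noise_drift_rel, self.noise_intensity_rel) < 0:
            raise ValueError("noise levels must be >= 0")
        if self.growth_mode not in ("isotropic", "linear_above_4", "mixture"):
            raise ValueError(f"unknown growth_mode: {self.growth_mode!r}")

    def noiseless(self) -> "EnsembleConfig":
        return replace(self, noise_mz_ppm=0.0, noise_drift_rel=0.0, noise_intensity_rel=0.0)


def charge_states(
    n: int, z_monomer: int = 3, z_max: int = 12, shift: int = 0
) -> list[tuple[int, float]]:
    """Candidate charges for state n with triangular weights (0.25/0.5/0.25).

    Charges are centred on ``round(z_monomer * n^(2/3)) + shift`` and clipped
    to ``z_max`` (the instrument/assignment charge cap); large states whose
    whole window exceeds the cap collapse onto ``z_max``. Elongated species
    expose more surface and so carry more charge: the generator hands the
    linear family a positive ``shift``.
    """
    center = max(1, round(z_monomer * n ** (2.0 / 3.0)) + shift)
    states = [(center - 1, 0.25), (center, 0.5), (center + 1, 0.25)]
    states = [(z, w) for z, w in states if 1 <= z <= z_max]
    if not states:
        states = [(z_max, 1.0)]
    total = sum(w for _, w in states)
    return [(z, w / total) for z, w in states]


def _family_weights(config: EnsembleConfig, n: int) -> tuple[float, float]:
    """(isotropic, linear) population weights for state n under the growth mode."""
    if config.growth_mode == "isotropic":
        return 1.0, 0.0
    if config.growth_mode == "linear_above_4":
        return (1.0, 0.0) if n <= 4 else (0.0, 1.0)
    if config.mixture_weights and n in config.mixture_weights:
        return config.mixture_weights[n]
    # default mixture mirrors the observed family structure: isotropic
    # dominates small states, the linear family takes over above n = 4
    if n <= 3:
        return 1.0, 0.0
    if n == 4:
        return 0.5, 0.5
    if n <= 6:
        return 0.3, 0.7
    return 0.0, 1.0


def _linear_law(config: EnsembleConfig) -> tuple[float, float]:
    """Slope/intercept of the planted linear family, continuous at n = 4."""
    anchor = config.monomer_ccs_z3
    slope = config.linear_slope_factor * anchor
    intercept = isotropic_ccs(anchor, 4) - slope * 4
    return slope, intercept


def planted_ccs(config: EnsembleConfig, n: int, family: str, z: int | None = None) -> float:
    """Ground-truth CCS for state n in the given family ('I2', 'I3' or 'L').

    In ``mixture`` mode the z = 2 monomer sits on the compact I2 anchor
    (``monomer_ccs_z2``); the idealized single-family modes keep every
    species on the I3 anchor so the stated world is exactly one curve.
    """
    if family == "L":
        slope, intercept = _linear_law(config)
        return slope * n + intercept
    if family == "I2" or (
        config.growth_mode == "mixture" and n == 1 and z == 2
    ):
        return isotropic_ccs(config.monomer_ccs_z2, n)
    return isotropic_ccs(config.monomer_ccs_z3, n)


def true_families(config: EnsembleConfig) -> list:
    """The planted growth-family objects (I2, I3, L as applicable)."""
    from .growth_families import GrowthFamily

    families = [
        GrowthFamily(kind="isotropic", anchor_charge=3, ccs_monomer=config.monomer_ccs_z3)
    ]
    if config.growth_mode == "mixture":
        families.insert(
            0,
            GrowthFamily(
                kind="isotropic", anchor_charge=2, ccs_monomer=config.monomer_ccs_z2, n_max=4
            ),
        )
    if config.growth_mode in ("linear_above_4", "mixture"):
        slope, intercept = _linear_law(config)
        families.append(GrowthFamily(kind="linear", slope=slope, intercept=intercept, n_min=4))
    return families


def generate_ensemble(
    config: EnsembleConfig,
    calibration: CalibrationModel,
) -> tuple[list[SpectralFeature], pd.DataFrame]:
    """Peak list plus ground-truth table for one variant.

    Each planted species is one (n, z, family) with abundance
    ``decay^(n-1) * boost(n >= threshold) * z_weight * family_weight``;
    its m/z is (n*M + z*H)/z, its CCS comes from the family law, and its
    drift time from inverting the calibration. Noise: additive Gaussian on
    m/z (ppm-scaled) and drift time, multiplicative lognormal on intensity.
    A fixed seed makes the output byte-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    features: list[SpectralFeature] = []
    truth_rows = []
    for n in range(1, config.max_state + 1):
        state_abundance = config.abundance_decay ** (n - 1)
        if n >= config.boost_threshold:
            state_abundance *= config.large_state_boost
        w_iso, w_lin = _family_weights(config, n)
        for family, w_fam in (("I3", w_iso), ("L", w_lin)):
            if w_fam <= 0:
                continue
            shift = config.linear_charge_shift if family == "L" else 0
            zs = charge_states(n, config.z_monomer, shift=shift)
            if not zs:
                raise ValueError(f"empty charge-state set for n={n}")
            for z, w_z in zs:
                fam_label = (
                    "I2"
                    if family == "I3" and config.growth_mode == "mixture" and n == 1 and z == 2
                    else family
                )
                ccs_true = planted_ccs(config, n, fam_label, z)
                abundance = config.base_intensity * state_abundance * w_fam * w_z
                mz_true = oligomer_mz(n, z, config.monomer_mass)
                drift_true = invert_calibration(calibration, ccs_true, mz_true, z)
                mz = mz_true + rng.normal(0.0, config.noise_mz_ppm * 1e-6 * mz_true) if config.noise_mz_ppm else mz_true
                drift = drift_true + rng.normal(0.0, config.noise_drift_rel * drift_true) if config.noise_drift_rel else drift_true
                intensity = abundance * rng.lognormal(0.0, config.noise_intensity_rel) if config.noise_intensity_rel else abundance
                features.append(SpectralFeature(mz=float(mz), drift_time=float(drift), intensity=float(intensity)))
                truth_rows.append(
                    {
                        "n": n,
                        "z": z,
                        "family": fam_label,
                        "mz": mz_true,
                        "ccs_a2": ccs_true,
                        "drift_time_ms": drift_true,
                        "abundance": abundance,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["n", "z", "family", "mz", "ccs_a2", "drift_time_ms", "abundance"],
    )
    return features, truth


def assignments_from_truth(truth: pd.DataFrame, variant_label: str = ""):
    """Ground-truth table as exact OligomerAssignment objects.

    Bypasses deconvolution entirely: each planted (n, z) species becomes one
    assignment carrying its true CCS and abundance. Used to exercise
    downstream operations (profiles, relative intensities) against the
    stated world with zero assignment error.
    """
    from .oligomer_assignment import OligomerAssignment

    out = []
    for row in truth.itertuples():
        feature = SpectralFeature(
            mz=float(row.mz), drift_time=float(row.drift_time_ms), intensity=float(row.abundance)
        )
        out.append(
            OligomerAssignment(
                n=int(row.n),
                z=int(row.z),
                ccs=float(row.ccs_a2),
                intensity_share=float(row.abundance),
                feature=feature,
                variant_label=variant_label,
                family=str(row.family),
            )
        )
    return out


def wt_like_config(seed: int = 0, **overrides) -> EnsembleConfig:
    """Wild-type-like ensemble: mixed growth families, no large-state boost."""
    return EnsembleConfig(growth_mode="mixture", large_state_boost=1.0, seed=seed, **overrides)


def cc_like_config(seed: int = 1, **overrides) -> EnsembleConfig:
    """Cross-linked-variant-like ensemble: 3x boost of states n >= 8."""
    return EnsembleConfig(
        growth_mode="mixture", large_state_boost=3.0, boost_threshold=8, seed=seed, **overrides
    )


DEFAULT_CALIBRANT_SPECIES: dict[str, tuple[float, tuple[int, ...]]] = {
    # mass (Da), charge states — mimics a melittin / ubiquitin /
    # beta-lactoglobulin ladder spanning the oligomer size scale
    "melittin": (2846.5, (3, 4)),
    "ubiquitin": (8565.8, (5, 6, 7)),
    "beta_lactoglobulin": (18363.0, (8, 9, 10)),
}


def generate_calibrants(
    true_a: float = 350.0,
    true_b: float = 0.55,
    species: dict[str, tuple[float, tuple[int, ...]]] | None = None,
    seed: int = 0,
    noise: float = 0.0,
    edc_coefficient_c: float = 1.41,
    drift_gas_mass: float = 28.0134,
) -> list[CalibrantRecord]:
    """Calibrant table whose drift times obey a known power law (A, B).

    Reference CCS values follow the globular scaling 3.8 * mass^(2/3) with a
    small per-charge expansion; drift times invert the power law exactly,
    then optional lognormal noise (relative sigma ``noise``) is applied.
    """
    if true_b <= 0:
        raise ValueError("true_b must be positive")
    species = species or DEFAULT_CALIBRANT_SPECIES
    model = CalibrationModel(
        power_coefficient_a=true_a,
        exponent_b=true_b,
        edc_coefficient_c=edc_coefficient_c,
        drift_gas_mass=drift_gas_mass,
    )
    rng = np.random.default_rng(seed)
    records = []
    for name, (mass, charges) in species.items():
        for z in charges:
            ccs = 3.8 * mass ** (2.0 / 3.0) * (1.0 + 0.02 * (z - min(charges)))
            mz = mass / z + PROTON_MASS
            drift = invert_calibration(model, ccs, mz, z)
            if noise:
                drift *= rng.lognormal(0.0, noise)
            records.append(
                CalibrantRecord(
                    species_name=name, charge=z, mass=mass, reference_ccs=ccs, drift_time=float(drift)
                )
            )
    return records


def generate_sphere_cluster(n: int, monomer_radius: float = 10.0, arrangement: str = "merged"):
    """Pseudo-atom oligomer models obeying exact spherical geometry.

    ``merged``: a single pseudo-atom of radius r1 * n^(1/3), conserving
    volume V_n = n * V_1 exactly — the isotropic-growth oracle. ``chain``:
    n touching monomer spheres in a line — the elongated-growth oracle.
    """
    from .structure_analysis import AtomRecord, StructureModel

    if n < 1:
        raise ValueError("n must be >= 1")
    if arrangement == "merged":
        atoms = [
            AtomRecord(
                element="X",
                coordinates=(0.0, 0.0, 0.0),
                radius=monomer_radius * n ** (1.0 / 3.0),
                residue_name="SPH",
            )
        ]
    elif arrangement == "chain":
        atoms = [
            AtomRecord(
                element="X",
                coordinates=(2.0 * monomer_radius * i, 0.0, 0.0),
                radius=monomer_radius,
                residue_index=i + 1,
                residue_name="SPH",
            )
            for i in range(n)
        ]
    else:
        raise ValueError(f"unknown arrangement: {arrangement!r}")
    return StructureModel(atoms)
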
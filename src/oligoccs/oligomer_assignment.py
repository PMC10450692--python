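"""Oligomeric-state / charge-state (n/z) assignment of native MS features.

Oligomers of a single peptide overlap in m/z whenever their n/z ratios agree
(1/2 = 2/4 = 3/6 = ...), so a peak's m/z alone fixes only the ratio, not the
state. The ion-mobility dimension breaks the tie: each candidate (n, z)
implies a calibrated CCS, and candidates whose CCS sits near a fitted growth
family's prediction for state n are favoured. Intensity is split among
candidates with Gaussian weights in relative CCS deviation, conserving total
signal exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ccs_calibration import PROTON_MASS, CalibrationModel, apply_calibration

#: Average residue masses (Da) of the 20 standard amino acids.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Aβ(1-40) one-letter sequence; the monomer all defaults are sized to.
ABETA40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"

#: Molar extinction coefficient of a single tyrosine at 280 nm (M^-1 cm^-1);
#: Aβ has one Tyr (Y10) and no Trp, so this is the whole-peptide epsilon.
TYROSINE_EXTINCTION = 1490.0

DEFAULT_TOLERANCE_PPM = 200.0
DEFAULT_CCS_KERNEL_WIDTH = 0.03
DEFAULT_MAX_N = 12
DEFAULT_MAX_Z = 12

PEAKLIST_COLUMNS = ["mz", "drift_time_ms", "intensity"]


@dataclass(frozen=True)
class SpectralFeature:
    """One centroided IM-MS feature: m/z (Th), drift time (ms), intensity."""

    mz: float
    drift_time: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.drift_time <= 0:
            raise ValueError("mz and drift_time must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class OligomerAssignment:
    """A feature resolved to oligomer state n and charge z with its CCS share."""

    n: int
    z: int
    ccs: float
    intensity_share: float
    feature: SpectralFeature
    variant_label: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        if self.n < 1 or self.z < 1:
            raise ValueError("n and z must be >= 1")
        if self.ccs <= 0:
            raise ValueError("ccs must be positive")
        if self.intensity_share < 0:
            raise ValueError("intensity_share must be non-negative")


@dataclass
class VariantDataset:
    """All assignments for one peptide variant plus per-state intensity fractions."""

    variant_label: str
    monomer_sequence: str = ""
    monomer_mass: float = 0.0
    assignments: list[OligomerAssignment] = field(default_factory=list)
    unassigned: list[SpectralFeature] = field(default_factory=list)

    @property
    def relative_intensity_by_state(self) -> dict[int, float]:
        return relative_intensities(self.assignments)


def average_mass_from_sequence(sequence: str) -> float:
    """Average molecular mass (Da) of a peptide from its one-letter sequence."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    mass = WATER_MASS
    for letter in sequence.upper():
        try:
            mass += AVERAGE_RESIDUE_MASS[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter: {letter!r}") from None
    return mass


def oligomer_mz(n: int, z: int, monomer_mass: float) -> float:
    """Theoretical m/z of an [nM + zH]^z+ oligomer ion."""
    return (n * monomer_mass + z * PROTON_MASS) / z


def enumerate_nz(
    mz: float,
    monomer_mass: float,
    max_n: int = DEFAULT_MAX_N,
    max_z: int = DEFAULT_MAX_Z,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> list[tuple[int, int]]:
    """All (n, z) whose theoretical m/z is within tolerance_ppm, ascending n.

    Equal n/z ratios land on the same m/z, so a single peak typically returns
    the whole 1/2 = 2/4 = 3/6 ... ladder up to the caps.
    """
    if mz <= 0 or monomer_mass <= 0 or max_n < 1 or max_z < 1:
        raise ValueError("mz, monomer_mass, max_n, max_z must be positive")
    out = []
    for n in range(1, max_n + 1):
        for z in range(1, max_z + 1):
            theo = oligomer_mz(n, z, monomer_mass)
            if abs(mz - theo) <= tolerance_ppm * 1e-6 * theo:
                out.append((n, z))
    return out


def deconvolute(
    features: Sequence[SpectralFeature],
    model: CalibrationModel,
    families: Sequence["GrowthFamily"] | None = None,
    monomer_mass: float = 0.0,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    ccs_kernel_width: float = DEFAULT_CCS_KERNEL_WIDTH,
    max_n: int = DEFAULT_MAX_N,
    max_z: int = DEFAULT_MAX_Z,
    variant_label: str = "",
) -> tuple[list[OligomerAssignment], list[SpectralFeature]]:
    """Resolve each feature's intensity among its (n, z) candidates.

    With growth families supplied, each candidate's weight is a Gaussian
    kernel of the relative deviation between the feature's calibrated CCS
    (computed at the candidate's charge) and the closest family prediction
    for state n. Without families (bootstrap first pass) the lowest-n
    candidate takes the whole intensity. Total intensity is conserved
    exactly; candidate-less features are returned as unassigned, never
    dropped.
    """
    if monomer_mass <= 0:
        raise ValueError("monomer_mass must be positive")
    assignments: list[OligomerAssignment] = []
    unassigned: list[SpectralFeature] = []
    families = list(families) if families else []
    for feature in features:
        candidates = enumerate_nz(feature.mz, monomer_mass, max_n, max_z, tolerance_ppm)
        if not candidates:
            unassigned.append(feature)
            continue
        ccs_by_candidate = np.array(
            [apply_calibration(model, feature.drift_time, feature.mz, z) for _, z in candidates]
        )
        if not families:
            weights = np.zeros(len(candidates))
            weights[0] = 1.0  # candidates are ascending in n
        else:
            deviations = np.array(
                [
                    min(
                        (
                            abs(ccs - fam.predict(n)) / fam.predict(n)
                            for fam in families
                            if fam.covers(n)
                        ),
                        default=np.inf,
                    )
                    for (n, _), ccs in zip(candidates, ccs_by_candidate)
                ]
            )
            with np.errstate(over="ignore"):
                weights = np.exp(-0.5 * (deviations / ccs_kernel_width) ** 2)
            if weights.sum() == 0.0:  # all kernels underflow: keep best candidate
                weights[int(np.argmin(deviations))] = 1.0
        weights = weights / weights.sum()
        for (n, z), ccs, w in zip(candidates, ccs_by_candidate, weights):
            assignments.append(
                OligomerAssignment(
                    n=n,
                    z=z,
                    ccs=float(ccs),
                    intensity_share=float(w) * feature.intensity,
                    feature=feature,
                    variant_label=variant_label,
                )
            )
    return assignments, unassigned


def relative_intensities(assignments: Sequence[OligomerAssignment]) -> dict[int, float]:
    """Fraction of total assigned signal per oligomeric state n (sums to 1)."""
    if not assignments:
        raise ValueError("need at least one assignment")
    total = sum(a.intensity_share for a in assignments)
    if total <= 0:
        raise ValueError("total assigned intensity is zero")
    fractions: dict[int, float] = {}
    for a in assignments:
        fractions[a.n] = fractions.get(a.n, 0.0) + a.intensity_share
    return {n: v / total for n, v in sorted(fractions.items())}


def enrichment_ratio(
    variant_a: VariantDataset | Mapping[int, float],
    variant_b: VariantDataset | Mapping[int, float],
) -> dict[int, float]:
    """Per-state ratio rel_a(n) / rel_b(n); above 1 means enriched in a.

    States absent from the denominator are reported as NaN (undefined), not
    infinity.
    """
    rel_a = (
        variant_a.relative_intensity_by_state
        if isinstance(variant_a, VariantDataset)
        else dict(variant_a)
    )
    rel_b = (
        variant_b.relative_intensity_by_state
        if isinstance(variant_b, VariantDataset)
        else dict(variant_b)
    )
    out: dict[int, float] = {}
    for n in sorted(set(rel_a) | set(rel_b)):
        if n not in rel_a:
            continue
        if n not in rel_b or rel_b[n] == 0.0:
            out[n] = float("nan")
        else:
            out[n] = rel_a[n] / rel_b[n]
    return out


def concentration_from_absorbance(
    absorbance: float,
    path_length: float = 1.0,
    extinction: float = TYROSINE_EXTINCTION,
) -> float:
    """Beer-Lambert molar concentration c = A / (epsilon * l)."""
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if extinction <= 0 or path_length <= 0:
        raise ValueError("extinction and path_length must be positive")
    return absorbance / (extinction * path_length)


def read_peak_list(path: str | Path) -> list[SpectralFeature]:
    """Read a peak list (CSV/TSV, header mz,drift_time_ms,intensity)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision='round_trip')
    missing = set(PEAKLIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    return [
        SpectralFeature(mz=float(r.mz), drift_time=float(r.drift_time_ms), intensity=float(r.intensity))
        for r in df.itertuples()
    ]


def write_peak_list(features: Iterable[SpectralFeature], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"mz": f.mz, "drift_time_ms": f.drift_time, "intensity": f.intensity} for f in features],
        columns=PEAKLIST_COLUMNS,
    )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def assignments_from_frame(frame: pd.DataFrame) -> list[OligomerAssignment]:
    """Rebuild assignments from the tidy TSV table (drift times are not kept)."""
    out = []
    for r in frame.itertuples():
        feature = SpectralFeature(mz=float(r.mz), drift_time=1.0, intensity=float(r.intensity_share))
        out.append(
            OligomerAssignment(
                n=int(r.n), z=int(r.z), ccs=float(r.ccs_a2),
                intensity_share=float(r.intensity_share), feature=feature,
                variant_label=str(r.variant),
                family="" if pd.isna(r.family) else str(r.family),
            )
        )
    return out


def assignments_to_frame(assignments: Sequence[OligomerAssignment]) -> pd.DataFrame:
    """Assignments as a tidy table: variant,n,z,mz,ccs_a2,intensity_share,family."""
    return pd.DataFrame(
        [
            {
                "variant": a.variant_label,
                "n": a.n,
                "z": a.z,
                "mz": a.feature.mz,
                "ccs_a2": a.ccs,
                "intensity_share": a.intensity_share,
                "family": a.family,
            }
            for a in assignments
        ],
        columns=["variant", "n", "z", "mz", "ccs_a2", "intensity_share", "family"],
    )
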
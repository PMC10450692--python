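"""Oligomer growth-family fitting and classification.

A sphere that grows at constant density has volume V_n = n * V_1 and hence
cross section CCS_n = CCS_1 * n^(2/3): "isotropic" growth. Oligomer CCS
series that instead increase linearly with n indicate elongation along one
axis (extended, beta-sheet-like aggregates). This module fits both laws,
assigns each (n, z) species to its nearest family, and computes the
intensity-weighted deviation ratio of measured CCS against the theoretical
isotropic curve, with a piecewise-linear fit whose breakpoint is fixed at
n = 4 (the observed growth-regime change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .oligomer_assignment import OligomerAssignment

DEFAULT_MEMBERSHIP_TOLERANCE = 0.05
DEFAULT_LINEAR_NMIN = 4
DEFAULT_BREAKPOINT = 4


@dataclass
class GrowthFamily:
    """A parameterised growth law with its member (n, z) species.

    ``kind="isotropic"``: CCS(n) = ccs_monomer * n^(2/3), anchored at the
    compact monomer of charge ``anchor_charge`` (I2, I3, ...).
    ``kind="linear"``: CCS(n) = slope * n + intercept (family L).
    """

    kind: str
    anchor_charge: int | None = None
    ccs_monomer: float | None = None
    slope: float | None = None
    intercept: float | None = None
    n_min: int = 1
    n_max: int | None = None
    members: list[tuple[int, int, float]] = field(default_factory=list)  # (n, z, residual)

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic", "linear"):
            raise ValueError(f"unknown family kind: {self.kind!r}")
        if self.kind == "isotropic":
            if self.ccs_monomer is None or self.ccs_monomer <= 0:
                raise ValueError("isotropic family requires ccs_monomer > 0")
        else:
            if self.slope is None or self.slope <= 0:
                raise ValueError("linear family requires slope > 0")
            if self.intercept is None:
                self.intercept = 0.0

    @property
    def label(self) -> str:
        if self.kind == "isotropic":
            return f"I{self.anchor_charge}" if self.anchor_charge else "I"
        return "L"

    def covers(self, n: int) -> bool:
        """Whether state n lies in the family's domain of existence."""
        return n >= self.n_min and (self.n_max is None or n <= self.n_max)

    def predict(self, n: int) -> float:
        """Family-predicted CCS (A^2) for oligomeric state n."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.kind == "isotropic":
            return isotropic_ccs(self.ccs_monomer, n)
        return self.slope * n + self.intercept


def isotropic_ccs(ccs_monomer: float, n: int | float) -> float:
    """Spherical-growth CCS: ccs_monomer * n^(2/3)."""
    if ccs_monomer <= 0:
        raise ValueError("ccs_monomer must be positive")
    if np.any(np.asarray(n) < 1):
        raise ValueError("n must be >= 1")
    out = ccs_monomer * np.power(np.asarray(n, dtype=float), 2.0 / 3.0)
    return out if out.ndim else float(out)


def fit_growth_exponent(series: Sequence[tuple[float, float]]) -> float:
    """OLS slope of ln(ccs) on ln(n); 2/3 for spheres, 1 for lines."""
    series = list(series)
    ns = np.array([s[0] for s in series], dtype=float)
    ccs = np.array([s[1] for s in series], dtype=float)
    if np.unique(ns).size < 3:
        raise ValueError("need at least 3 distinct n")
    if np.any(ccs <= 0) or np.any(ns <= 0):
        raise ValueError("n and ccs must be positive")
    slope, _ = np.polyfit(np.log(ns), np.log(ccs), 1)
    return float(slope)


def fit_linear_family(
    series: Sequence[tuple[float, float]], n_min: int = DEFAULT_LINEAR_NMIN
) -> tuple[float, float]:
    """OLS line (slope, intercept) over states with n >= n_min."""
    pts = [(n, c) for n, c in series if n >= n_min]
    ns = np.array([p[0] for p in pts], dtype=float)
    ccs = np.array([p[1] for p in pts], dtype=float)
    if np.unique(ns).size < 2:
        raise ValueError(f"need >= 2 distinct states with n >= {n_min}")
    slope, intercept = np.polyfit(ns, ccs, 1)
    return float(slope), float(intercept)


def classify_families(
    assignments: Sequence[OligomerAssignment],
    families: Sequence[GrowthFamily],
    membership_tolerance: float = DEFAULT_MEMBERSHIP_TOLERANCE,
) -> dict[tuple[int, int], str]:
    """Assign each (n, z) to the family minimising relative CCS deviation.

    A species joins the closest family only if its relative deviation is
    within ``membership_tolerance``; otherwise it is labelled "unclassified".
    Deviations are intensity-weighted means per (n, z). Mutates each
    assignment's ``family`` label and each family's member list.
    """
    if not families:
        raise ValueError("need at least one fitted family")
    for fam in families:
        fam.members = []
    # intensity-weighted mean CCS per (n, z)
    acc: dict[tuple[int, int], list[float]] = {}
    for a in assignments:
        w, wc = acc.setdefault((a.n, a.z), [0.0, 0.0])
        acc[(a.n, a.z)] = [w + a.intensity_share, wc + a.intensity_share * a.ccs]
    labels: dict[tuple[int, int], str] = {}
    for (n, z), (w, wc) in sorted(acc.items()):
        ccs = wc / w if w > 0 else np.mean([a.ccs for a in assignments if (a.n, a.z) == (n, z)])
        devs = [
            abs(ccs - fam.predict(n)) / fam.predict(n) if fam.covers(n) else np.inf
            for fam in families
        ]
        best = int(np.argmin(devs))
        if devs[best] <= membership_tolerance:
            labels[(n, z)] = families[best].label
            families[best].members.append((n, z, devs[best]))
        else:
            labels[(n, z)] = "unclassified"
    for a in assignments:
        a.family = labels[(a.n, a.z)]
    return labels


def derive_families(
    assignments: Sequence[OligomerAssignment],
    linear_n_min: int = DEFAULT_LINEAR_NMIN,
) -> list[GrowthFamily]:
    """Build the I2/I3/L family hypotheses from first-pass assignments.

    Isotropic anchors are the most intense monomer species at z = 2 and
    z = 3 (the compact charge states). The linear family is fitted to the
    intensity-weighted mean CCS of the most populated charge state per
    n >= ``linear_n_min``. Families that cannot be anchored/fitted are
    simply omitted.
    """
    families: list[GrowthFamily] = []
    for anchor_z in (2, 3):
        monomers = [a for a in assignments if a.n == 1 and a.z == anchor_z]
        if monomers:
            best = max(monomers, key=lambda a: a.intensity_share)
            # the minor compact family is anchored on a single monomer state;
            # restrict its curve so a one-point family does not open spurious
            # deconvolution channels at high states (the major I3 family keeps
            # the full domain)
            n_max = 2 if anchor_z == 2 else None
            families.append(
                GrowthFamily(
                    kind="isotropic", anchor_charge=anchor_z,
                    ccs_monomer=best.ccs, n_max=n_max,
                )
            )
    # most populated charge state per n, intensity-weighted mean CCS
    per_nz: dict[tuple[int, int], list[float]] = {}
    for a in assignments:
        w, wc = per_nz.setdefault((a.n, a.z), [0.0, 0.0])
        per_nz[(a.n, a.z)] = [w + a.intensity_share, wc + a.intensity_share * a.ccs]
    series = []
    for n in sorted({n for n, _ in per_nz}):
        if n < linear_n_min:
            continue
        candidates = {z: v for (nn, z), v in per_nz.items() if nn == n and v[0] > 0}
        if not candidates:
            continue
        z_top = max(candidates, key=lambda z: candidates[z][0])
        w, wc = candidates[z_top]
        series.append((n, wc / w))
    try:
        slope, intercept = fit_linear_family(series, n_min=linear_n_min)
        if slope > 0:
            families.append(
                GrowthFamily(kind="linear", slope=slope, intercept=intercept, n_min=linear_n_min)
            )
    except ValueError:
        pass
    return families


@dataclass
class GrowthProfile:
    """Per-state deviation of measured CCS from theoretical isotropic growth."""

    weighted_ccs: dict[int, float]
    deviation_ratio: dict[int, float]
    fit_low: tuple[float, float] | None   # (slope, intercept) for n in [1, 4]
    fit_high: tuple[float, float] | None  # (slope, intercept) for n in [4, 10]
    i3_ccs_monomer: float
    breakpoint: int = DEFAULT_BREAKPOINT

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "n": n,
                "weighted_ccs_a2": self.weighted_ccs[n],
                "i3_ccs_a2": isotropic_ccs(self.i3_ccs_monomer, n),
                "ratio": self.deviation_ratio[n],
            }
            for n in sorted(self.weighted_ccs)
        ]
        return pd.DataFrame(rows, columns=["n", "weighted_ccs_a2", "i3_ccs_a2", "ratio"])


def deviation_ratio_profile(
    assignments: Sequence[OligomerAssignment],
    i3_family: GrowthFamily,
    breakpoint: int = DEFAULT_BREAKPOINT,
    n_max_fit: int = 10,
) -> GrowthProfile:
    """Intensity-weighted mean CCS per state over its theoretical isotropic CCS.

    Ratios of 1 mean perfectly spherical growth. Two OLS lines are fitted to
    the (n, ratio) points, one on [1, breakpoint] and one on
    [breakpoint, n_max_fit]; the breakpoint is fixed, not estimated. States
    with zero total intensity are skipped.
    """
    if i3_family.kind != "isotropic":
        raise ValueError("profile requires an isotropic reference family")
    weighted: dict[int, float] = {}
    acc: dict[int, list[float]] = {}
    for a in assignments:
        w, wc = acc.setdefault(a.n, [0.0, 0.0])
        acc[a.n] = [w + a.intensity_share, wc + a.intensity_share * a.ccs]
    for n, (w, wc) in sorted(acc.items()):
        if w <= 0:
            continue
        weighted[n] = wc / w
    ratios = {
        n: ccs / isotropic_ccs(i3_family.ccs_monomer, n) for n, ccs in weighted.items()
    }

    def _fit(lo: int, hi: int) -> tuple[float, float] | None:
        pts = [(n, r) for n, r in ratios.items() if lo <= n <= hi]
        if len({n for n, _ in pts}) < 2:
            return None
        slope, intercept = np.polyfit(
            [float(n) for n, _ in pts], [r for _, r in pts], 1
        )
        return float(slope), float(intercept)

    return GrowthProfile(
        weighted_ccs=weighted,
        deviation_ratio=ratios,
        fit_low=_fit(1, breakpoint),
        fit_high=_fit(breakpoint, n_max_fit),
        i3_ccs_monomer=float(i3_family.ccs_monomer),
        breakpoint=breakpoint,
    )
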
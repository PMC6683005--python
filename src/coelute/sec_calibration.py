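"""SEC apparent-mass calibration.

Standards of known mass elute at characteristic fractions; log10(mass)
is close to linear in fraction over the column's fractionation range, so
a least-squares line through (peak_fraction, log10 mass_kda) converts any
fitted peak fraction into an apparent mass M_app.  R_app = M_app /
M_monomer summarizes a protein's oligomerization state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from coelute.io_profiles import CalibrationStandard


@dataclass(frozen=True)
class CalibrationModel:
    """Linear model log10(M_app) = slope * fraction + intercept."""

    slope: float
    intercept: float
    fraction_range: tuple[float, float]
    exclusion_limit_kda: float  # mass at the void / earliest calibrated fraction
    r_squared: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "fraction_range": list(self.fraction_range),
            "exclusion_limit_kda": self.exclusion_limit_kda,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            fraction_range=tuple(d["fraction_range"]),
            exclusion_limit_kda=d["exclusion_limit_kda"],
            r_squared=d.get("r_squared", float("nan")),
        )


def fit_calibration(standards: list[CalibrationStandard]) -> CalibrationModel:
    """Least-squares line of log10(mass) on peak fraction.

    Requires >= 2 standards at distinct fractions with mass strictly
    decreasing in fraction (larger species elute earlier).
    """
    if len(standards) < 2:
        raise ValueError("need >= 2 calibration standards")
    pts = sorted(standards, key=lambda s: s.peak_fraction)
    fracs = np.array([s.peak_fraction for s in pts])
    masses = np.array([s.mass_kda for s in pts])
    if len(np.unique(fracs)) < len(fracs):
        raise ValueError("calibration standards must have distinct peak fractions")
    if not np.all(np.diff(masses) < 0):
        raise ValueError("standard mass must decrease with peak fraction")
    if len(pts) == 2:
        slope = (np.log10(masses[1]) - np.log10(masses[0])) / (fracs[1] - fracs[0])
        intercept = np.log10(masses[0]) - slope * fracs[0]
        r2 = 1.0
    else:
        res = stats.linregress(fracs, np.log10(masses))
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    if slope >= 0:
        raise ValueError("calibration slope must be negative")
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        fraction_range=(float(fracs[0]), float(fracs[-1])),
        exclusion_limit_kda=float(masses[0]),
        r_squared=float(r2),
    )


def apparent_mass(fraction: float, model: CalibrationModel) -> tuple[float, str]:
    """Apparent mass (kDa) at a peak fraction, with a range flag.

    Returns (M_app, flag) where flag is '' inside the calibrated range,
    '>=exclusion_limit' before the first standard (void-proximal) and
    'extrapolated' past the last standard.
    """
    m_app = float(10.0 ** (model.slope * fraction + model.intercept))
    lo, hi = model.fraction_range
    if fraction < lo:
        return m_app, ">=exclusion_limit"
    if fraction > hi:
        return m_app, "extrapolated"
    return m_app, ""


def inverse_fraction(mass_kda: float, model: CalibrationModel) -> float:
    """Peak fraction at which a species of the given mass elutes."""
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    return (np.log10(mass_kda) - model.intercept) / model.slope


def r_app(m_app: float, m_monomer: float) -> float:
    """Apparent-to-monomer mass ratio; NaN propagates missing monomer mass."""
    if np.isnan(m_app) or np.isnan(m_monomer):
        return float("nan")
    if m_app <= 0 or m_monomer <= 0:
        raise ValueError("masses must be positive")
    return m_app / m_monomer
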
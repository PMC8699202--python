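"""CCS to drift-time conversion and least-squares instrument calibration.

For a drift-tube instrument, the Mason-Schamp relation makes the drift time
proportional to Omega * sqrt(mu) / z up to instrument constants, where Omega
is the CCS, mu = m*M/(M+m) the ion/buffer-gas reduced mass and z the charge:

    t_d = A * Omega * sqrt(mu) / z + B

A and B absorb pressure, tube length, field strength etc. and are fitted by
ordinary least squares against reference drift times.  A variant that is
linear in mu (t_d = A * Omega * mu / z + B) is selectable; A and B are
refitted either way, so the choice only changes the mass weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: monoisotopic mass of N2, the usual drift gas, in Da
NITROGEN_MASS = 28.006148

SQRT_MU = "sqrt-mu"
LINEAR_MU = "linear-mu"


@dataclass(frozen=True)
class DriftCalibration:
    """Instrument parameters for the CCS -> drift-time conversion."""

    A: float
    B: float
    gas_mass: float = NITROGEN_MASS
    form: str = SQRT_MU

    def __post_init__(self) -> None:
        if self.gas_mass <= 0:
            raise ValueError("neutral gas mass must be positive")
        if self.form not in (SQRT_MU, LINEAR_MU):
            raise ValueError(f"unknown calibration form {self.form!r}")


def reduced_mass(M, m):
    """Reduced mass m*M/(M+m) in Da."""
    M = np.asarray(M, dtype=np.float64)
    if np.any(M <= 0) or m <= 0:
        raise ValueError("masses must be positive")
    return m * M / (M + m)


def _regressor(ccs, z, M, gas_mass: float, form: str) -> np.ndarray:
    mu = reduced_mass(M, gas_mass)
    factor = np.sqrt(mu) if form == SQRT_MU else mu
    return np.asarray(ccs, dtype=np.float64) * factor / np.asarray(z, dtype=np.float64)


def ccs_to_drift(ccs, z, M, cal: DriftCalibration):
    """Drift time in seconds for CCS (A^2), charge z and ion mass M (Da)."""
    return cal.A * _regressor(ccs, z, M, cal.gas_mass, cal.form) + cal.B


def drift_to_ccs(td, z, M, cal: DriftCalibration):
    """Invert :func:`ccs_to_drift` for the CCS."""
    if cal.A == 0:
        raise ValueError("calibration slope A = 0 cannot be inverted")
    mu = reduced_mass(M, cal.gas_mass)
    factor = np.sqrt(mu) if cal.form == SQRT_MU else mu
    return (np.asarray(td, dtype=np.float64) - cal.B) * np.asarray(z, dtype=np.float64) / (
        cal.A * factor
    )


def fit_calibration(
    ccs_pred,
    z,
    M,
    td_ref,
    gas_mass: float = NITROGEN_MASS,
    form: str = SQRT_MU,
) -> DriftCalibration:
    """Least-squares fit of A (slope) and B (intercept) to reference drift times."""
    x = _regressor(ccs_pred, z, M, gas_mass, form)
    y = np.asarray(td_ref, dtype=np.float64)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least 2 distinct regressor values to fit A and B")
    res = stats.linregress(x, y)
    return DriftCalibration(A=float(res.slope), B=float(res.intercept), gas_mass=gas_mass, form=form)


def drift_report_by_charge(
    ccs_pred,
    z,
    M,
    td_ref,
    gas_mass: float = NITROGEN_MASS,
    form: str = SQRT_MU,
) -> dict[int, dict[str, float]]:
    """Fit A/B globally, then report R^2 and MSE of drift times per charge state."""
    z = np.asarray(z)
    cal = fit_calibration(ccs_pred, z, M, td_ref, gas_mass=gas_mass, form=form)
    td_hat = ccs_to_drift(ccs_pred, z, M, cal)
    td_ref = np.asarray(td_ref, dtype=np.float64)
    out: dict[int, dict[str, float]] = {}
    for zi in np.unique(z):
        mask = z == zi
        if mask.sum() < 2:
            warnings.warn(f"charge {zi}: fewer than 2 records, skipped", stacklevel=2)
            continue
        resid = td_hat[mask] - td_ref[mask]
        ss_tot = float(np.sum((td_ref[mask] - td_ref[mask].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        out[int(zi)] = {
            "r2": r2,
            "mse": float(np.mean(resid**2)),
            "n": int(mask.sum()),
        }
    return out
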
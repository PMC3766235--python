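"""Closed-form GFR estimating equations and the CKD stage grouping rule.

Implements the re-expressed 4-variable and 6-variable MDRD equations
(IDMS-traceable creatinine calibration) and the three-band CKD stage
grouping used throughout the validation pipeline:

* stage I/II  : GFR >= 60 mL/min/1.73 m^2
* stage III   : 30 <= GFR < 60
* stage IV/V  : GFR < 30

All estimator functions accept scalars or NumPy arrays and broadcast.
Serum creatinine is mg/dL throughout; no unit conversion is performed.
"""

from __future__ import annotations

import enum
import warnings

import numpy as np

__all__ = [
    "StageGroup",
    "stage_group",
    "stage_groups",
    "egfr_mdrd4",
    "egfr_mdrd6",
    "add_estimates",
]

#: Plausible serum creatinine range (mg/dL); values outside trigger a warning
#: rather than an error, to catch accidental umol/L inputs.
SCR_PLAUSIBLE = (0.1, 30.0)


class StageGroup(enum.Enum):
    """CKD stage grouping by GFR band."""

    I_II = "I_II"
    III = "III"
    IV_V = "IV_V"

    @property
    def ordinal(self) -> int:
        """Ordinal encoding: I/II -> 1, III -> 2, IV/V -> 3."""
        return {"I_II": 1, "III": 2, "IV_V": 3}[self.value]

    @classmethod
    def from_ordinal(cls, k: int) -> "StageGroup":
        return {1: cls.I_II, 2: cls.III, 3: cls.IV_V}[k]


def stage_group(gfr: float) -> StageGroup:
    """Map a GFR value (mL/min/1.73 m^2) to its CKD stage group.

    >>> stage_group(60.0).value
    'I_II'
    >>> stage_group(30.0).value
    'III'
    >>> stage_group(29.999).value
    'IV_V'
    """
    gfr = float(gfr)
    if not np.isfinite(gfr) or gfr <= 0:
        raise ValueError(f"GFR must be positive and finite, got {gfr}")
    if gfr >= 60.0:
        return StageGroup.I_II
    if gfr >= 30.0:
        return StageGroup.III
    return StageGroup.IV_V


def stage_groups(gfr: np.ndarray) -> np.ndarray:
    """Vectorized :func:`stage_group`; returns an array of ordinal codes 1/2/3."""
    gfr = np.asarray(gfr, dtype=float)
    if np.any(~np.isfinite(gfr)) or np.any(gfr <= 0):
        raise ValueError("all GFR values must be positive and finite")
    return np.where(gfr >= 60.0, 1, np.where(gfr >= 30.0, 2, 3))


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite")
    return arr


def _warn_scr_units(scr: np.ndarray) -> None:
    lo, hi = SCR_PLAUSIBLE
    if np.any(scr < lo) or np.any(scr > hi):
        warnings.warn(
            f"serum creatinine outside the plausible mg/dL range {SCR_PLAUSIBLE}; "
            "check that inputs are not umol/L",
            UserWarning,
            stacklevel=3,
        )


def egfr_mdrd4(scr, age, female=False, black=False):
    """Re-expressed 4-variable MDRD estimate of GFR (mL/min/1.73 m^2).

    eGFR4 = 175 * SCr^-1.154 * Age^-0.203 * 0.742[female] * 1.212[black]

    Parameters
    ----------
    scr : float or array
        Serum creatinine, mg/dL.
    age : float or array
        Age in years.
    female, black : bool or array of bool
        Demographic factors (multiplicative).
    """
    scr = _check_positive("scr", scr)
    age = _check_positive("age", age)
    _warn_scr_units(scr)
    female = np.asarray(female, dtype=bool)
    black = np.asarray(black, dtype=bool)
    out = (
        175.0
        * scr ** -1.154
        * age ** -0.203
        * np.where(female, 0.742, 1.0)
        * np.where(black, 1.212, 1.0)
    )
    return out if out.ndim else float(out)


def egfr_mdrd6(scr, age, bun, alb, female=False, black=False):
    """Re-expressed 6-variable MDRD estimate of GFR (mL/min/1.73 m^2).

    eGFR6 = 161.5 * SCr^-0.999 * Age^-0.176 * BUN^-0.170 * Alb^+0.318
            * 0.762[female] * 1.18[black]

    Parameters
    ----------
    scr : float or array
        Serum creatinine, mg/dL.
    age : float or array
        Age in years.
    bun : float or array
        Blood urea nitrogen, mg/dL.
    alb : float or array
        Serum albumin, g/dL.
    female, black : bool or array of bool
        Demographic factors (multiplicative).
    """
    scr = _check_positive("scr", scr)
    age = _check_positive("age", age)
    bun = _check_positive("bun", bun)
    alb = _check_positive("alb", alb)
    _warn_scr_units(scr)
    female = np.asarray(female, dtype=bool)
    black = np.asarray(black, dtype=bool)
    out = (
        161.5
        * scr ** -0.999
        * age ** -0.176
        * bun ** -0.170
        * alb ** 0.318
        * np.where(female, 0.762, 1.0)
        * np.where(black, 1.18, 1.0)
    )
    return out if out.ndim else float(out)


def add_estimates(frame):
    """Append ``egfr4`` and ``egfr6`` columns to a cohort DataFrame.

    Expects the cohort CSV column layout (``scr_mg_dl``, ``age_years``,
    ``female``, ``black``, ``bun_mg_dl``, ``alb_g_dl``). Returns a copy.
    """
    out = frame.copy()
    out["egfr4"] = egfr_mdrd4(
        out["scr_mg_dl"].to_numpy(),
        out["age_years"].to_numpy(),
        out["female"].to_numpy(dtype=bool),
        out["black"].to_numpy(dtype=bool),
    )
    out["egfr6"] = egfr_mdrd6(
        out["scr_mg_dl"].to_numpy(),
        out["age_years"].to_numpy(),
        out["bun_mg_dl"].to_numpy(),
        out["alb_g_dl"].to_numpy(),
        out["female"].to_numpy(dtype=bool),
        out["black"].to_numpy(dtype=bool),
    )
    return out
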
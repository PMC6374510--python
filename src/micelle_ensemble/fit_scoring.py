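"""Goodness-of-fit between calculated and experimental SAXS profiles.

The headline statistic is a Tanimoto-type Jaccard index on the
log-intensities of the two profiles,

    J = sum(x*y) / (sum(x^2) + sum(y^2) - sum(x*y)),   x = log I, y = log Ic,

which equals 1 exactly when the log-profiles coincide and, for profiles
whose logs are all positive, lies in [0, 1] (Cauchy-Schwarz).  Because
the index is not invariant to the arbitrary units of I, calculated
profiles are least-squares scaled onto the experimental one first, and
both are then rescaled so the experimental maximum sits at a fixed
reference intensity; base-10 logs are used throughout.  The
error-weighted reduced chi^2 is provided as the conventional reference
metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .saxs_forward import ScatteringProfile

#: experimental maximum is scaled to this intensity before taking logs,
#: keeping log-intensities positive over the usual SAXS dynamic range
REFERENCE_INTENSITY = 1.0e4

LOG_BASE = 10.0


@dataclass
class FitResult:
    """Outcome of comparing one calculated profile with experiment."""

    jaccard: float
    chi2_reduced: float      # NaN when experimental sigmas are absent
    scale: float
    n_points: int

    def as_dict(self) -> dict:
        return {"jaccard": self.jaccard, "chi2_reduced": self.chi2_reduced,
                "scale": self.scale, "n_points": self.n_points}


def align_profiles(calc: ScatteringProfile, exp: ScatteringProfile
                   ) -> Tuple[ScatteringProfile, ScatteringProfile, int]:
    """Interpolate ``calc`` onto the experimental q-grid.

    Experimental points with non-positive or non-finite intensity are
    dropped (count returned); interpolation is linear in log I vs q.
    The calculated range must cover the experimental one.
    """
    keep = np.isfinite(exp.intensity) & (exp.intensity > 0)
    if exp.sigma is not None:
        keep &= np.isfinite(exp.sigma)
    n_dropped = int((~keep).sum())
    qe = exp.q[keep]
    if len(qe) < 2:
        raise ValueError("fewer than 2 usable experimental points")
    if qe[0] < calc.q[0] - 1e-12 or qe[-1] > calc.q[-1] + 1e-12:
        raise ValueError(
            f"calculated q-range [{calc.q[0]:g}, {calc.q[-1]:g}] does not cover "
            f"experimental [{qe[0]:g}, {qe[-1]:g}]")
    if np.any(calc.intensity <= 0):
        raise ValueError("calculated profile must be strictly positive")
    log_i = np.interp(qe, calc.q, np.log(calc.intensity))
    calc_on_grid = ScatteringProfile(qe, np.exp(log_i), label=calc.label)
    exp_f = ScatteringProfile(qe, exp.intensity[keep],
                              None if exp.sigma is None else exp.sigma[keep],
                              exp.label)
    return calc_on_grid, exp_f, n_dropped


def scale_to(calc: ScatteringProfile, exp: ScatteringProfile
             ) -> Tuple[ScatteringProfile, float]:
    """Least-squares multiplicative scale of ``calc`` onto ``exp``:
    s = sum(Ie*Ic) / sum(Ic^2)."""
    if len(calc) != len(exp):
        raise ValueError("profiles must be aligned first")
    denom = float(np.dot(calc.intensity, calc.intensity))
    if denom == 0.0:
        raise ValueError("zero calculated profile")
    s = float(np.dot(exp.intensity, calc.intensity)) / denom
    return calc.scaled(s), s


def jaccard_index(exp: ScatteringProfile, calc: ScatteringProfile,
                  log_base: float = LOG_BASE) -> float:
    """The Jaccard/Tanimoto similarity of two log-intensity profiles.

    Both profiles must be strictly positive and on the same grid;
    scaling/normalisation is the caller's responsibility (see
    :func:`fit_profiles`).
    """
    if len(exp) != len(calc):
        raise ValueError("length mismatch")
    if np.any(exp.intensity <= 0) or np.any(calc.intensity <= 0):
        raise ValueError("non-positive intensity: logarithm undefined")
    x = np.log(exp.intensity) / np.log(log_base)
    y = np.log(calc.intensity) / np.log(log_base)
    xy = float(np.dot(x, y))
    denom = float(np.dot(x, x) + np.dot(y, y)) - xy
    if denom == 0.0:  # both logs identically zero
        return 1.0
    return xy / denom


def chi2_reduced(exp: ScatteringProfile, calc: ScatteringProfile) -> float:
    """Reduced chi^2 with the fitted scale: sum(((Ie - s*Ic)/sig)^2)/(N-1)."""
    if exp.sigma is None or np.any(exp.sigma <= 0):
        raise ValueError("chi^2 requires strictly positive experimental sigmas")
    scaled, _ = scale_to(calc, exp)
    resid = (exp.intensity - scaled.intensity) / exp.sigma
    return float(np.dot(resid, resid) / (len(exp) - 1))


def fit_profiles(exp: ScatteringProfile, calc: ScatteringProfile,
                 scale: bool = True,
                 reference: Optional[float] = REFERENCE_INTENSITY,
                 log_base: float = LOG_BASE) -> FitResult:
    """Full comparison pipeline: align, scale, normalise, score.

    Returns the Jaccard index (log base ``log_base``), the reduced
    chi^2 when sigmas are available (NaN otherwise), the fitted scale
    and the number of compared points.
    """
    calc_a, exp_f, _ = align_profiles(calc, exp)
    if scale:
        calc_s, s = scale_to(calc_a, exp_f)
    else:
        calc_s, s = calc_a, 1.0
    if reference is not None:
        norm = reference / exp_f.intensity.max()
        exp_n, calc_n = exp_f.scaled(norm), calc_s.scaled(norm)
    else:
        exp_n, calc_n = exp_f, calc_s
    j = jaccard_index(exp_n, calc_n, log_base=log_base)
    if exp_f.sigma is not None and np.all(exp_f.sigma > 0):
        chi2 = chi2_reduced(exp_f, calc_a)
    else:
        chi2 = float("nan")
    return FitResult(jaccard=j, chi2_reduced=chi2, scale=s, n_points=len(exp_f))
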
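"""Circular statistics shared by the gait and EMG analyses.

Angles live on the unit circle; summaries are computed from the mean unit
vector.  The resultant length ``R`` plays the role of an (inverse) spread
measure: R -> 1 for tightly concentrated samples, R -> 0 for dispersed ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CircularSummary",
    "WWTestResult",
    "circular_summary",
    "circular_kde",
    "watson_williams",
    "wrap_to_2pi",
    "wrap_to_pi",
    "estimate_kappa",
]

_R_UNDEFINED_TOL = 1e-8


def wrap_to_2pi(angles):
    """Wrap angles to [0, 2*pi)."""
    r = np.asarray(angles, dtype=float) % (2.0 * np.pi)
    # a % 2pi can round up to exactly 2pi for tiny negative inputs
    return np.where(r >= 2.0 * np.pi, 0.0, r)


def wrap_to_pi(angles):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(angles, dtype=float)
    return -((-a + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean direction and mean resultant length of an angle sample.

    Attributes
    ----------
    theta_hat : float
        Mean direction in [0, 2*pi).  ``nan`` when undefined (R ~ 0).
    R : float
        Mean resultant length in [0, 1].
    n : int
        Sample size.
    defined : bool
        False when the resultant vanishes and the mean direction is
        meaningless (e.g. two antipodal points).
    """

    theta_hat: float
    R: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class WWTestResult:
    """Watson-Williams test for equality of circular mean directions."""

    F: float
    df1: int
    df2: int
    p_value: float
    pooled_R: float
    assumption_ok: bool


def circular_summary(angles) -> CircularSummary:
    """Mean direction and resultant length of a sample of angles (radians).

    theta_hat is the argument and R the modulus of the mean unit vector
    ``mean(exp(i*angle))``.  When R is numerically zero the mean direction is
    undefined and the summary is flagged.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size < 1:
        raise ValueError("circular_summary requires at least one angle")
    z = np.exp(1j * a).mean()
    R = float(np.abs(z))
    if R < _R_UNDEFINED_TOL:
        warnings.warn("resultant length ~ 0: circular mean undefined", stacklevel=2)
        return CircularSummary(theta_hat=float("nan"), R=R, n=a.size, defined=False)
    return CircularSummary(theta_hat=float(np.angle(z) % (2.0 * np.pi)), R=R, n=a.size)


def circular_kde(angles, kappa: float = 20.0, n_grid: int = 360):
    """von Mises kernel density estimate on the circle.

    Parameters
    ----------
    angles : array-like
        Sample of angles in radians.
    kappa : float
        Concentration of the von Mises kernel (larger = narrower kernel).
    n_grid : int
        Number of evaluation points over [0, 2*pi).

    Returns
    -------
    grid, density : ndarray
        Evaluation grid and density; the density integrates to 1 over the
        circle.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("circular_kde requires at least two angles")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    grid = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    # mean of von Mises kernels centred on each sample
    dens = stats.vonmises.pdf(grid[:, None], kappa, loc=a[None, :]).mean(axis=1)
    return grid, dens


def estimate_kappa(rbar: float) -> float:
    """Maximum-likelihood-style estimate of the von Mises concentration.

    Fisher's (1993) piecewise approximation from the mean resultant length.
    """
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    denom = rbar**3 - 4.0 * rbar**2 + 3.0 * rbar
    return 1.0 / denom if denom > 0 else 1e6


def watson_williams(*groups, assumption_floor: float = 0.45) -> WWTestResult:
    """Watson-Williams F test for a common mean direction across groups.

    Parametric one-way comparison of circular means assuming von Mises
    samples with a shared concentration.  Uses the standard correction
    factor ``1 + 3/(8*kappa_hat)``.  The test is unreliable when the pooled
    mean resultant length is small; ``assumption_ok`` is False when the
    weighted pooled R falls below ``assumption_floor``.

    Parameters
    ----------
    *groups : array-like
        Two or more samples of angles in radians, each with n >= 2.

    Returns
    -------
    WWTestResult
    """
    if len(groups) < 2:
        raise ValueError("watson_williams requires at least two groups")
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in arrs:
        if g.size < 2:
            raise ValueError("each group needs at least two angles")
    k = len(arrs)
    ns = np.array([g.size for g in arrs])
    N = int(ns.sum())
    # per-group and grand resultant vector lengths (sums, not means)
    Rj = np.array([np.abs(np.exp(1j * g).sum()) for g in arrs])
    R = float(np.abs(np.concatenate([np.exp(1j * g) for g in arrs]).sum()))
    rbar_w = float(Rj.sum() / N)
    kappa = estimate_kappa(rbar_w)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    df1, df2 = k - 1, N - k
    denom = N - Rj.sum()
    if denom <= 0:  # all angles identical within groups
        F = np.inf if Rj.sum() - R > 0 else 0.0
    else:
        F = float(correction * df2 * (Rj.sum() - R) / (df1 * denom))
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return WWTestResult(
        F=F,
        df1=df1,
        df2=df2,
        p_value=p,
        pooled_R=rbar_w,
        assumption_ok=rbar_w >= assumption_floor,
    )
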
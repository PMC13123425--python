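"""Polymer elasticity and force-dependent unfolding kinetics.

This module implements the two physical models at the heart of the
force-spectroscopy analysis:

* the worm-like chain (WLC) in the Marko-Siggia interpolation, which maps
  the end-to-end extension ``x`` of a polymer of contour length ``Lc`` and
  persistence length ``Lp`` to the entropic restoring force

  .. math::

      F(x) = \\frac{k_B T}{L_p}\\left[\\frac{1}{4}(1 - x/L_c)^{-2}
             - \\frac{1}{4} + \\frac{x}{L_c}\\right]

* Bell-Evans unfolding kinetics, where the unfolding rate grows
  exponentially with the applied force,

  .. math::

      k(F) = k_0 \\, e^{\\gamma F / k_B T},

  with ``k0`` the unstressed unfolding rate (1/s) and ``gamma`` the
  distance from the folded state to the transition state (nm).

Under a constant loading rate ``r`` (pN/s) the Bell-Evans model yields the
Evans-Ritchie expression for the most probable rupture force,
``F* = (kBT/gamma) * ln(gamma * r / (k0 * kBT))``, which is affine in
``ln r`` with slope ``kBT/gamma``.

Two Bell-Evans parameter sets (e.g. a protein alone versus the protein with
a ligand bound) generically cross at a single force

  ``F_x = kBT * ln(k0_a / k0_b) / (gamma_b - gamma_a)``,

below which the second state unfolds more slowly (is mechanically
stabilized) and above which it unfolds faster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import KBT_25C
from .errors import (
    DegenerateParametersError,
    DomainError,
    FitError,
    InputError,
)

__all__ = [
    "WLCParams",
    "BellEvansParams",
    "WLCFit",
    "BellEvansFit",
    "wlc_force",
    "wlc_extension",
    "wlc_fractional_extension",
    "fit_wlc",
    "bell_rate",
    "evans_ritchie_force",
    "fit_bell_evans",
    "crossover_force",
    "stability_profile",
]


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters.

    Attributes
    ----------
    contour_length : float
        Lc, maximum end-to-end length of the chain (nm). Must be > 0.
    persistence_length : float
        Lp, bending-stiffness length scale (nm). Must be > 0.
    kBT : float
        Thermal energy (pN·nm), default 4.114 (25 C).
    """

    contour_length: float
    persistence_length: float
    kBT: float = KBT_25C

    def __post_init__(self) -> None:
        if not self.contour_length > 0:
            raise DomainError(f"contour_length must be > 0, got {self.contour_length}")
        if not self.persistence_length > 0:
            raise DomainError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )
        if not self.kBT > 0:
            raise DomainError(f"kBT must be > 0, got {self.kBT}")


@dataclass(frozen=True)
class BellEvansParams:
    """Bell-Evans unfolding kinetics parameters.

    Attributes
    ----------
    k0 : float
        Unstressed unfolding rate (1/s). Must be >= 0.
    gamma : float
        Energy-barrier position, i.e. distance to the transition state
        along the pulling coordinate (nm). Must be >= 0.
    kBT : float
        Thermal energy (pN·nm), default 4.114 (25 C).
    """

    k0: float
    gamma: float
    kBT: float = KBT_25C

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise DomainError(f"k0 must be >= 0, got {self.k0}")
        if self.gamma < 0:
            raise DomainError(f"gamma must be >= 0, got {self.gamma}")
        if not self.kBT > 0:
            raise DomainError(f"kBT must be > 0, got {self.kBT}")


def _as_array(value, name: str):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def _scalar_or_array(result, template):
    if np.ndim(template) == 0:
        return float(result)
    return result


def wlc_force(extension, params: WLCParams):
    """Entropic force of a worm-like chain at a given extension.

    Marko-Siggia interpolation. Accepts a scalar or array extension (nm),
    returns force (pN). The extension must lie in ``[0, Lc)``; the force
    diverges as ``x -> Lc``.
    """
    x = _as_array(extension, "extension")
    if np.any(x < 0):
        raise DomainError("extension must be non-negative")
    if np.any(x >= params.contour_length):
        raise DomainError(
            f"extension must be below the contour length {params.contour_length} nm"
        )
    t = x / params.contour_length
    force = (params.kBT / params.persistence_length) * (
        0.25 / (1.0 - t) ** 2 - 0.25 + t
    )
    return _scalar_or_array(force, extension)


def wlc_fractional_extension(force, persistence_length: float, kBT: float = KBT_25C):
    """Fractional extension ``x/Lc`` of a WLC held at a given force.

    Inverts the Marko-Siggia relation by vectorized bisection on the
    monotone dimensionless form. The result is exact to double precision
    (80 bisection steps). Accepts scalar or array force (pN).
    """
    f = _as_array(force, "force")
    if np.any(f < 0):
        raise DomainError("force must be non-negative")
    target = f * persistence_length / kBT
    lo = np.zeros_like(target)
    hi = np.full_like(target, 1.0 - 1e-15)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        value = 0.25 / (1.0 - mid) ** 2 - 0.25 + mid
        below = value < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = np.where(target == 0.0, 0.0, 0.5 * (lo + hi))
    return _scalar_or_array(out, force)


def wlc_extension(force, params: WLCParams):
    """Extension (nm) of a worm-like chain at a given force (pN).

    Numerical inverse of :func:`wlc_force` by bracketed bisection on
    ``[0, Lc)``; satisfies ``wlc_force(wlc_extension(F)) == F`` to better
    than 1e-9 relative.
    """
    frac = wlc_fractional_extension(force, params.persistence_length, params.kBT)
    return frac * params.contour_length


@dataclass(frozen=True)
class WLCFit:
    """Result of a worm-like-chain least-squares fit."""

    params: WLCParams
    stderr: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "model": "worm_like_chain",
            "contour_length_nm": self.params.contour_length,
            "persistence_length_nm": self.params.persistence_length,
            "kBT_pN_nm": self.params.kBT,
            "stderr": dict(self.stderr),
            "residual_sd_pN": self.residual_sd,
            "n_points": self.n_points,
        }


def fit_wlc(
    force,
    extension,
    kBT: float = KBT_25C,
    initial_guess: tuple[float, float] | None = None,
    objective: str = "force",
    fix_Lp: float | None = None,
) -> WLCFit:
    """Fit contour length (and persistence length) to force-extension data.

    Least squares with ``kBT`` held fixed. Two residual conventions are
    offered because optical-tweezer data carry noise on both channels:

    * ``objective="force"`` (default) minimizes force residuals of the
      Marko-Siggia form — the conventional presentation of a WLC fit;
    * ``objective="extension"`` minimizes extension residuals of the
      inverse relation ``x = Lc * xi(F; Lp)``. Prefer this when the
      dominant noise is on the extension channel (e.g. extension jumps
      measured at matched force), where it is the statistically consistent
      regression direction.

    ``fix_Lp`` holds the persistence length at a known value and fits only
    the contour length (with the extension objective this reduces to a
    closed-form linear regression through the origin in ``xi``).

    Unless overridden, the free fit starts at ``Lc = 1.05 * max(extension)``
    and ``Lp = 0.4 nm``, with ``Lc`` bounded just above the largest observed
    extension so the Marko-Siggia form stays defined throughout. On
    noise-free data every route recovers the generating parameters exactly.

    Parameters
    ----------
    force, extension : array-like
        Matched samples in pN and nm. At least 4 points are required.
    initial_guess : (Lc, Lp), optional

    Returns
    -------
    WLCFit
        Fitted :class:`WLCParams`, asymptotic standard errors, and the
        residual standard deviation (pN or nm, per the objective).
    """
    f = _as_array(force, "force")
    x = _as_array(extension, "extension")
    if f.shape != x.shape or f.ndim != 1:
        raise InputError("force and extension must be 1-D arrays of equal length")
    if f.size < 4:
        raise InputError(f"need at least 4 points to fit a WLC, got {f.size}")
    if np.any(x < 0) or np.any(f < 0):
        raise DomainError("force and extension must be non-negative")
    if objective not in ("force", "extension"):
        raise InputError(f"unknown objective {objective!r}")

    n_free = 1 if fix_Lp is not None else 2
    dof = max(f.size - n_free, 1)

    if fix_Lp is not None and objective == "extension":
        # x = Lc * xi(F; Lp): linear in Lc, solved in closed form
        xi = wlc_fractional_extension(f, fix_Lp, kBT)
        denom = float(np.sum(xi**2))
        if denom == 0.0:
            raise FitError("all forces are zero; contour length is unidentifiable")
        lc = float(np.sum(xi * x) / denom)
        resid_sd = float(np.sqrt(np.sum((x - lc * xi) ** 2) / dof))
        return WLCFit(
            params=WLCParams(lc, fix_Lp, kBT),
            stderr={
                "contour_length_nm": resid_sd / math.sqrt(denom),
                "persistence_length_nm": None,
            },
            residual_sd=resid_sd,
            n_points=int(f.size),
        )

    xmax = float(x.max())
    if initial_guess is not None:
        lc0, lp0 = initial_guess
    else:
        lc0, lp0 = 1.05 * xmax, 0.4
    lc0 = max(lc0, 1.05 * xmax)

    if objective == "force":

        def model(x, Lc, Lp):
            t = x / Lc
            return (kBT / Lp) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)

        m = lmfit.Model(model, independent_vars=["x"])
        pars = m.make_params(Lc=lc0, Lp=lp0)
        pars["Lc"].set(min=xmax * (1.0 + 1e-9))
        target, indep = f, {"x": x}
    else:

        def model(F, Lc, Lp):
            return Lc * wlc_fractional_extension(F, Lp, kBT)

        m = lmfit.Model(model, independent_vars=["F"])
        pars = m.make_params(Lc=lc0, Lp=lp0)
        pars["Lc"].set(min=1e-6)
        target, indep = x, {"F": f}

    pars["Lp"].set(min=1e-4, max=1e3)
    if fix_Lp is not None:
        pars["Lp"].set(value=fix_Lp, vary=False)
    result = m.fit(target, pars, **indep)
    if not result.success:
        raise FitError(f"WLC fit did not converge: {result.message}")

    return WLCFit(
        params=WLCParams(
            contour_length=float(result.params["Lc"].value),
            persistence_length=float(result.params["Lp"].value),
            kBT=kBT,
        ),
        stderr={
            "contour_length_nm": result.params["Lc"].stderr,
            "persistence_length_nm": result.params["Lp"].stderr,
        },
        residual_sd=float(math.sqrt(result.chisqr / dof)),
        n_points=int(f.size),
    )


def bell_rate(force, params: BellEvansParams):
    """Bell-Evans unfolding rate ``k(F) = k0 * exp(gamma*F/kBT)`` in 1/s."""
    f = _as_array(force, "force")
    if np.any(f < 0):
        raise DomainError("force must be non-negative")
    rate = params.k0 * np.exp(params.gamma * f / params.kBT)
    return _scalar_or_array(rate, force)


def evans_ritchie_force(loading_rate, params: BellEvansParams):
    """Most probable rupture force at a constant loading rate (pN).

    ``F* = (kBT/gamma) * ln(gamma * r / (k0 * kBT))``. When the logarithm's
    argument is <= 1 the analytic expression would be negative, which is
    unphysical; the result is clamped to 0 with a warning (the rupture-force
    distribution then peaks at zero force).
    """
    if params.gamma <= 0 or params.k0 <= 0:
        raise DomainError("evans_ritchie_force requires gamma > 0 and k0 > 0")
    r = _as_array(loading_rate, "loading_rate")
    if np.any(r <= 0):
        raise DomainError("loading_rate must be positive")
    arg = params.gamma * r / (params.k0 * params.kBT)
    with np.errstate(invalid="ignore"):
        fstar = (params.kBT / params.gamma) * np.log(arg)
    if np.any(arg <= 1.0):
        warnings.warn(
            "loading rate below k0*kBT/gamma: most probable force clamped to 0",
            stacklevel=2,
        )
        fstar = np.where(arg <= 1.0, 0.0, fstar)
    return _scalar_or_array(fstar, loading_rate)


@dataclass(frozen=True)
class BellEvansFit:
    """Result of a dynamic-force-spectroscopy (Evans-Ritchie) fit."""

    params: BellEvansParams
    stderr: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    n_points: int = 0
    method: str = "nls"

    def to_dict(self) -> dict:
        return {
            "model": "bell_evans",
            "k0_per_s": self.params.k0,
            "gamma_nm": self.params.gamma,
            "kBT_pN_nm": self.params.kBT,
            "stderr": dict(self.stderr),
            "residual_sd_pN": self.residual_sd,
            "n_points": self.n_points,
            "method": self.method,
        }


def _linear_bell_evans(logr, f, kBT):
    """Linear regression of F* on ln(r), back-transformed to (k0, gamma).

    Returns (k0, gamma, k0_se, gamma_se). Used both as the closed-form
    estimator and as the starting point for the nonlinear fit.
    """
    if logr.size > 2:
        (slope, intercept), cov = np.polyfit(logr, f, 1, cov=True)
    else:
        slope, intercept = np.polyfit(logr, f, 1)
        cov = None
    if slope <= 0:
        raise FitError(
            "most probable force does not increase with loading rate; "
            "Bell-Evans parameters are undefined"
        )
    gamma = kBT / slope
    k0 = (gamma / kBT) * math.exp(-intercept / slope)
    if cov is not None:
        b_se = math.sqrt(cov[0, 0])
        a_se = math.sqrt(cov[1, 1])
        ab_cov = cov[0, 1]
        gamma_se = kBT * b_se / slope**2
        # delta method for k0(a, b) = (1/b) * exp(-a/b)
        dk_da = -k0 / slope
        dk_db = k0 * (intercept / slope**2 - 1.0 / slope)
        var = dk_da**2 * a_se**2 + dk_db**2 * b_se**2 + 2 * dk_da * dk_db * ab_cov
        k0_se = math.sqrt(max(var, 0.0))
    else:
        gamma_se = k0_se = None
    return k0, gamma, k0_se, gamma_se


def fit_bell_evans(
    loading_rates,
    forces,
    kBT: float = KBT_25C,
    method: str = "nls",
) -> BellEvansFit:
    """Fit Bell-Evans kinetics to (loading rate, most probable force) data.

    Parameters
    ----------
    loading_rates, forces : array-like
        Loading rates (pN/s, > 0, at least two distinct values) and the
        most probable rupture forces (pN) observed at them.
    method : {"nls", "linear"}
        ``"nls"`` (default) runs nonlinear least squares on the
        Evans-Ritchie relation, seeded by the linear-regression estimate;
        ``"linear"`` returns the regression of F* on ln(r) back-transformed
        to (k0, gamma). On noise-free data the two agree exactly.
    """
    r = _as_array(loading_rates, "loading_rates")
    f = _as_array(forces, "forces")
    if r.shape != f.shape or r.ndim != 1:
        raise InputError("loading_rates and forces must be 1-D arrays of equal length")
    if r.size < 2:
        raise InputError("need at least 2 rate points")
    if np.any(r <= 0):
        raise DomainError("loading rates must be positive")
    if np.unique(r).size < 2:
        raise InputError("all loading rates are identical; the slope is undefined")

    logr = np.log(r)
    k0_lin, gamma_lin, k0_se, gamma_se = _linear_bell_evans(logr, f, kBT)
    dof = max(r.size - 2, 1)

    if method == "linear":
        pred = (kBT / gamma_lin) * np.log(gamma_lin * r / (k0_lin * kBT))
        resid_sd = float(np.sqrt(np.sum((f - pred) ** 2) / dof))
        return BellEvansFit(
            params=BellEvansParams(k0=k0_lin, gamma=gamma_lin, kBT=kBT),
            stderr={"k0_per_s": k0_se, "gamma_nm": gamma_se},
            residual_sd=resid_sd,
            n_points=int(r.size),
            method="linear",
        )
    if method != "nls":
        raise InputError(f"unknown method {method!r}; use 'nls' or 'linear'")

    def model(r, k0, gamma):
        return (kBT / gamma) * np.log(gamma * r / (k0 * kBT))

    m = lmfit.Model(model, independent_vars=["r"])
    pars = m.make_params(k0=k0_lin, gamma=gamma_lin)
    pars["k0"].set(min=1e-12)
    pars["gamma"].set(min=1e-6)
    result = m.fit(f, pars, r=r)
    if not result.success:
        raise FitError(f"Bell-Evans fit did not converge: {result.message}")
    return BellEvansFit(
        params=BellEvansParams(
            k0=float(result.params["k0"].value),
            gamma=float(result.params["gamma"].value),
            kBT=kBT,
        ),
        stderr={
            "k0_per_s": result.params["k0"].stderr,
            "gamma_nm": result.params["gamma"].stderr,
        },
        residual_sd=float(math.sqrt(result.chisqr / dof)),
        n_points=int(r.size),
        method="nls",
    )


def crossover_force(params_a: BellEvansParams, params_b: BellEvansParams) -> float:
    """Force at which two Bell-Evans rate curves intersect (pN).

    ``F_x = kBT * ln(k0_a/k0_b) / (gamma_b - gamma_a)``. The value is
    returned signed: a negative result means the curves only cross at an
    unphysical (negative) force. Below a positive crossover the state with
    the smaller ``k0`` unfolds more slowly (is stabilized); above it the
    ordering reverses.
    """
    if abs(params_a.kBT - params_b.kBT) > 1e-9:
        raise InputError(
            f"mismatched kBT: {params_a.kBT} vs {params_b.kBT}; "
            "both parameter sets must share the thermal energy"
        )
    if params_a.k0 <= 0 or params_b.k0 <= 0:
        raise DomainError("crossover requires both k0 > 0")
    if abs(params_a.gamma - params_b.gamma) < 1e-12:
        raise DegenerateParametersError(
            "equal barrier positions: the rate curves are parallel in log "
            "space and never cross (or coincide everywhere)"
        )
    return (
        params_a.kBT
        * math.log(params_a.k0 / params_b.k0)
        / (params_b.gamma - params_a.gamma)
    )


def stability_profile(
    force_grid,
    reference: BellEvansParams,
    bound: BellEvansParams,
):
    """Ratio of unfolding rates ``k_bound(F) / k_reference(F)`` on a force grid.

    Values below 1 mean the bound state is mechanically stabilized relative
    to the reference at that force; values above 1 mean it is destabilized.
    The ratio passes through 1 exactly at :func:`crossover_force`.
    """
    f = _as_array(force_grid, "force_grid")
    if f.size == 0:
        raise InputError("force grid must be non-empty")
    if np.any(f < 0):
        raise DomainError("forces must be non-negative")
    if abs(reference.kBT - bound.kBT) > 1e-9:
        raise InputError("mismatched kBT between reference and bound parameters")
    return _scalar_or_array(
        np.asarray(bell_rate(f, bound)) / np.asarray(bell_rate(f, reference)),
        force_grid,
    )
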
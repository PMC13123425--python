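"""Dose-response (Hill) analysis of binding titrations.

Models a microscale-thermophoresis-style titration: a serially diluted
ligand is mixed with a fluorescent target and the normalized signal follows
a saturation-binding (Hill) isotherm

.. math::

    S(c) = \\text{baseline} + \\text{amplitude}
           \\cdot \\frac{c^{n}}{EC_{50}^{n} + c^{n}}

The fitted EC50 is the half-maximal ligand concentration; for a Hill
coefficient near 1 it is conventionally reported as the Kd of the
interaction. Flat series (no concentration dependence beyond noise) are
flagged ``no_binding`` instead of returning a meaningless EC50.

The affinity-fold statistic compares two dissociation constants as
``Kd_wildtype / Kd_mutant`` rounded half-up to one decimal, so values above
1 mean the mutant binds more tightly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DomainError, FitError, InputError

__all__ = [
    "TitrationSeries",
    "HillFit",
    "serial_dilution",
    "hill_response",
    "simulate_titration",
    "fit_hill",
    "fold_affinity_change",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Concentration-response pairs for one titration replicate.

    Concentrations are molar, strictly positive, and stored in descending
    order (the natural order of a serial dilution).
    """

    concentrations: np.ndarray
    signal: np.ndarray
    replicate_id: str = "rep-1"
    target_label: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "signal", sig)
        if conc.shape != sig.shape or conc.ndim != 1:
            raise InputError("concentrations and signal must match in length")
        if np.any(conc <= 0):
            raise InputError("concentrations must be strictly positive")
        if np.any(np.diff(conc) >= 0):
            raise InputError("concentrations must be strictly decreasing")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill isotherm with convergence and no-binding flags."""

    ec50: float
    hill_n: float
    amplitude: float
    baseline: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    no_binding: bool = False
    residual_sd: float = float("nan")
    n_points: int = 0

    @property
    def kd_equivalent(self) -> float | None:
        """EC50 reported as a Kd when the Hill coefficient is near 1
        (within 25%), the regime where the isotherm is a simple binding
        curve; ``None`` otherwise or when no binding was detected."""
        if self.no_binding or abs(self.hill_n - 1.0) > 0.25:
            return None
        return self.ec50

    def to_dict(self) -> dict:
        return {
            "model": "hill",
            "ec50_M": None if self.no_binding else self.ec50,
            "hill_n": self.hill_n,
            "amplitude": self.amplitude,
            "baseline": self.baseline,
            "stderr": dict(self.stderr),
            "converged": self.converged,
            "no_binding": self.no_binding,
            "residual_sd": self.residual_sd,
            "n_points": self.n_points,
        }


def serial_dilution(top: float, steps: int = 15, factor: float = 2.0) -> np.ndarray:
    """Concentrations of a serial dilution, highest first.

    ``steps`` dilutions by ``factor`` give ``steps + 1`` concentrations, the
    last equal to ``top / factor**steps`` (a 15-step 2-fold series spans
    down to 1/32768 of the top concentration).
    """
    if not top > 0:
        raise InputError("top concentration must be positive")
    if steps < 0:
        raise InputError("steps must be >= 0")
    if not factor > 1:
        raise InputError("dilution factor must be > 1")
    return top / factor ** np.arange(steps + 1, dtype=float)


def hill_response(
    conc,
    ec50: float,
    hill_n: float = 1.0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
):
    """Hill saturation signal at one or more concentrations (molar)."""
    if not ec50 > 0:
        raise DomainError("ec50 must be positive")
    if not hill_n > 0:
        raise DomainError("hill coefficient must be positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be non-negative")
    cn = c**hill_n
    out = baseline + amplitude * cn / (ec50**hill_n + cn)
    return float(out) if np.ndim(conc) == 0 else out


def simulate_titration(
    ec50: float,
    hill_n: float = 1.0,
    top: float = 500e-9,
    steps: int = 15,
    noise_sd: float = 0.02,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    target_label: str = "",
    replicate_id: str = "rep-1",
) -> TitrationSeries:
    """Simulate one titration: Hill signal on a serial-dilution schedule
    plus i.i.d. Gaussian noise. Defaults emulate a 15-step 2-fold dilution
    from a 500 nM top concentration with 2% noise on a unit-amplitude
    normalized signal."""
    conc = serial_dilution(top, steps=steps)
    signal = hill_response(conc, ec50, hill_n, amplitude, baseline)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=conc.shape)
    return TitrationSeries(
        concentrations=conc,
        signal=signal,
        replicate_id=replicate_id,
        target_label=target_label,
    )


def fit_hill(
    series: TitrationSeries,
    hill_bounds: tuple[float, float] = (0.3, 4.0),
) -> HillFit:
    """Fit the Hill isotherm to a titration series.

    Least squares with EC50, Hill coefficient, amplitude and baseline free
    (the Hill coefficient bounded to ``hill_bounds``). Requires at least 6
    points spanning more than 2 decades of concentration. A series whose
    fitted amplitude is smaller than 3 times the residual standard
    deviation carries no detectable concentration dependence and is flagged
    ``no_binding`` (its EC50 is not interpretable).
    """
    c = series.concentrations
    s = series.signal
    if c.size < 6:
        raise InputError("need at least 6 titration points")
    if math.log10(c.max() / c.min()) <= 2.0:
        raise InputError("titration must span more than 2 decades of concentration")

    def model(c, ec50, n, amplitude, baseline):
        cn = c**n
        return baseline + amplitude * cn / (ec50**n + cn)

    geo_mean = math.sqrt(c.max() * c.min())
    m = lmfit.Model(model, independent_vars=["c"])
    pars = m.make_params(
        ec50=geo_mean,
        n=1.0,
        amplitude=float(s.max() - s.min()),
        baseline=float(s[-1]),  # lowest concentration is last
    )
    pars["ec50"].set(min=c.min() / 1e4, max=c.max() * 1e4)
    pars["n"].set(min=hill_bounds[0], max=hill_bounds[1])
    result = m.fit(s, pars, c=c)
    if not result.success:
        raise FitError(f"Hill fit did not converge: {result.message}")

    dof = max(c.size - 4, 1)
    residual_sd = float(math.sqrt(result.chisqr / dof))
    amplitude = float(result.params["amplitude"].value)
    no_binding = abs(amplitude) < 3.0 * residual_sd + 1e-12
    return HillFit(
        ec50=float(result.params["ec50"].value),
        hill_n=float(result.params["n"].value),
        amplitude=amplitude,
        baseline=float(result.params["baseline"].value),
        stderr={
            "ec50_M": result.params["ec50"].stderr,
            "hill_n": result.params["n"].stderr,
            "amplitude": result.params["amplitude"].stderr,
            "baseline": result.params["baseline"].stderr,
        },
        converged=True,
        no_binding=no_binding,
        residual_sd=residual_sd,
        n_points=int(c.size),
    )


def fold_affinity_change(kd_wildtype: float, kd_mutant: float) -> float:
    """Fold change in affinity of a mutant relative to wild type.

    ``Kd_wildtype / Kd_mutant`` rounded half-up to one decimal; values
    above 1 mean the mutant binds more tightly.
    """
    if kd_wildtype <= 0 or kd_mutant <= 0:
        raise InputError("dissociation constants must be positive")
    ratio = kd_wildtype / kd_mutant
    return math.floor(ratio * 10.0 + 0.5) / 10.0
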
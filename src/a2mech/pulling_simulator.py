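"""Synthetic optical-tweezer pulling experiments with known ground truth.

The simulator produces constant-loading-rate force ramps applied to a
protein with one or more sequential unfolding transitions. Each transition
follows Bell-Evans kinetics, so under a ramp ``F(t) = F0 + r*t`` the
survival probability has a closed form and both the rupture-force density

.. math::

    p(F) = \\frac{k(F)}{r}
           \\exp\\!\\left[-\\frac{k_0 k_B T}{\\gamma r}
           \\left(e^{\\gamma F/k_B T} - 1\\right)\\right]

and its CDF are available analytically. Rupture forces are drawn by
inverse-CDF sampling, and trace-level transitions by integrating the hazard
in closed form against an exponential waiting threshold — exact in
distribution, with no time-discretization bias.

Mechanically, each trace is a chain of a stiff fixed-contour "folded
baseline" (standing in for the DNA handle plus folded protein) and an
unfolded polymer whose contour length grows by a fixed increment at every
transition, both described by worm-like chains. At a rupture at force
``F_r`` the extension jumps by ``dLc * xi(F_r)`` (``xi`` the fractional WLC
extension) and the force relaxes by an effective-stiffness-scaled amount
before the ramp resumes — the sawtooth signature that event detection
looks for.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .constants import KBT_25C
from .errors import DomainError, InputError, NoEventError
from .force_models import BellEvansParams, wlc_fractional_extension

__all__ = [
    "UnfoldingState",
    "UnfoldingPathway",
    "PullingProtocol",
    "GroundTruthEvent",
    "PullingTrace",
    "ExperimentResult",
    "rupture_force_cdf",
    "rupture_force_pdf",
    "simulate_rupture_forces",
    "simulate_trace",
    "simulate_experiment",
]


@dataclass(frozen=True)
class UnfoldingState:
    """One unfolding transition: a contour-length gain and its kinetics."""

    delta_Lc: float
    kinetics: BellEvansParams

    def __post_init__(self) -> None:
        if not self.delta_Lc > 0:
            raise DomainError(f"delta_Lc must be > 0, got {self.delta_Lc}")


@dataclass(frozen=True)
class UnfoldingPathway:
    """Sequential unfolding pathway plus the elasticity of the construct.

    ``states`` are traversed in order; the unfolded contour length grows by
    ``delta_Lc`` at each transition. The unfolded polypeptide is a WLC with
    persistence length ``unfolded_Lp``; the folded construct (DNA handle +
    folded domain) is a stiff WLC of fixed contour length ``folded_Lc`` and
    persistence length ``folded_Lp`` whose compliance sets the pre-rupture
    baseline.
    """

    states: tuple[UnfoldingState, ...]
    unfolded_Lp: float = 0.28
    folded_Lc: float = 20.0
    folded_Lp: float = 10.0
    kBT: float = KBT_25C

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 1:
            raise InputError("pathway needs at least one unfolding transition")
        if not (self.unfolded_Lp > 0 and self.folded_Lp > 0 and self.folded_Lc > 0):
            raise DomainError("persistence and contour lengths must be positive")

    @property
    def total_contour_gain(self) -> float:
        """Fully-unfolded contour-length gain (nm), the sum of increments."""
        return sum(s.delta_Lc for s in self.states)

    @classmethod
    def single_step(
        cls,
        delta_Lc: float = 55.3,
        k0: float = 0.15,
        gamma: float = 0.71,
        unfolded_Lp: float = 0.28,
        kBT: float = KBT_25C,
        **kwargs,
    ) -> "UnfoldingPathway":
        """Two-state (one-transition) pathway; defaults are the A2-alone
        condition (Lc gain 55.3 nm, k0 0.15/s, gamma 0.71 nm)."""
        return cls(
            states=(UnfoldingState(delta_Lc, BellEvansParams(k0, gamma, kBT)),),
            unfolded_Lp=unfolded_Lp,
            kBT=kBT,
            **kwargs,
        )

    @classmethod
    def two_step(
        cls,
        increments: tuple[float, float] = (27.0, 28.3),
        kinetics: tuple[tuple[float, float], tuple[float, float]] = (
            (0.3, 0.71),
            (0.15, 0.71),
        ),
        unfolded_Lp: float = 0.28,
        kBT: float = KBT_25C,
        **kwargs,
    ) -> "UnfoldingPathway":
        """Three-state (two-transition) pathway emulating the low-ligand
        regime: a first, faster transition that ruptures at lower force and
        a second, control-like transition at higher force. The default
        increments (27.0 + 28.3 nm) sum to the one-step total of 55.3 nm.
        """
        states = tuple(
            UnfoldingState(dlc, BellEvansParams(k0, g, kBT))
            for dlc, (k0, g) in zip(increments, kinetics)
        )
        return cls(states=states, unfolded_Lp=unfolded_Lp, kBT=kBT, **kwargs)


@dataclass(frozen=True)
class PullingProtocol:
    """Force-ramp acquisition settings.

    ``effective_stiffness`` (pN/nm) converts the extension released at a
    rupture into the instantaneous force drop seen by the trap; it is a
    phenomenological stand-in for the series stiffness of the trap + handle,
    not a mechanical model of the beads.
    """

    loading_rate: float = 10.0
    sampling_interval: float = 0.002
    max_force: float = 30.0
    noise_sd_force: float = 0.3
    noise_sd_extension: float = 2.0
    effective_stiffness: float = 0.25

    def __post_init__(self) -> None:
        if not self.loading_rate > 0:
            raise DomainError("loading_rate must be positive")
        if not self.sampling_interval > 0:
            raise DomainError("sampling_interval must be positive")
        if not self.max_force > 0:
            raise DomainError("max_force must be positive")
        if self.noise_sd_force < 0 or self.noise_sd_extension < 0:
            raise DomainError("noise standard deviations must be >= 0")
        if not self.effective_stiffness >= 0:
            raise DomainError("effective_stiffness must be >= 0")

    @classmethod
    def from_speed(
        cls, pulling_speed: float, effective_stiffness: float = 0.25, **kwargs
    ) -> "PullingProtocol":
        """Build a protocol from a pulling speed (nm/s); the loading rate is
        speed times the effective stiffness."""
        return cls(
            loading_rate=pulling_speed * effective_stiffness,
            effective_stiffness=effective_stiffness,
            **kwargs,
        )


@dataclass(frozen=True)
class GroundTruthEvent:
    """Exact simulated transition: time (s), force (pN), contour gain (nm)."""

    time: float
    force: float
    delta_Lc: float


@dataclass(frozen=True)
class PullingTrace:
    """One recorded pull: sampled time/force/extension channels plus, for
    simulated traces, the exact ground-truth event log."""

    trace_id: str
    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    loading_rate: float
    ground_truth_events: tuple[GroundTruthEvent, ...] = ()
    truncated: bool = False
    protocol: PullingProtocol | None = None

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.force) == len(self.extension)):
            raise InputError("time, force and extension must have equal length")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise InputError(f"trace {self.trace_id!r}: time must be strictly increasing")


def _check_ramp(kinetics: BellEvansParams, loading_rate: float) -> None:
    if kinetics.k0 == 0:
        raise NoEventError("k0 = 0: the protein never unfolds")
    if not loading_rate > 0:
        raise DomainError("loading_rate must be positive")


def rupture_force_cdf(force, kinetics: BellEvansParams, loading_rate: float):
    """Closed-form CDF of the first rupture force under a ramp from zero."""
    _check_ramp(kinetics, loading_rate)
    f = np.asarray(force, dtype=float)
    k0, g, kBT = kinetics.k0, kinetics.gamma, kinetics.kBT
    if g > 0:
        hazard = (k0 * kBT / (g * loading_rate)) * np.expm1(g * f / kBT)
    else:
        hazard = k0 * f / loading_rate
    out = -np.expm1(-np.where(f > 0, hazard, 0.0))
    return float(out) if np.ndim(force) == 0 else out


def rupture_force_pdf(force, kinetics: BellEvansParams, loading_rate: float):
    """Closed-form density of the first rupture force under a ramp."""
    _check_ramp(kinetics, loading_rate)
    f = np.asarray(force, dtype=float)
    k0, g, kBT = kinetics.k0, kinetics.gamma, kinetics.kBT
    rate = k0 * np.exp(g * f / kBT)
    if g > 0:
        hazard = (k0 * kBT / (g * loading_rate)) * np.expm1(g * f / kBT)
    else:
        hazard = k0 * f / loading_rate
    out = np.where(f >= 0, (rate / loading_rate) * np.exp(-hazard), 0.0)
    return float(out) if np.ndim(force) == 0 else out


def simulate_rupture_forces(
    kinetics: BellEvansParams,
    loading_rate: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. first-rupture forces by inverse-CDF sampling.

    Exact draws from the analytic rupture-force distribution; reproducible
    for a fixed ``seed`` (or an explicit ``rng``).
    """
    _check_ramp(kinetics, loading_rate)
    if n < 1:
        raise InputError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(int(n))
    k0, g, kBT = kinetics.k0, kinetics.gamma, kinetics.kBT
    if g > 0:
        c = g * loading_rate / (k0 * kBT)
        return (kBT / g) * np.log(1.0 - c * np.log1p(-u))
    return -(loading_rate / k0) * np.log1p(-u)


def _transition_force(F0: float, kin: BellEvansParams, r: float, threshold: float):
    """Force at which the integrated hazard along a ramp starting at F0
    reaches an Exp(1) threshold. Closed-form inversion of the cumulative
    hazard; returns +inf only in the untriggerable k0 = 0 case."""
    k0, g, kBT = kin.k0, kin.gamma, kin.kBT
    if k0 == 0:
        return np.inf
    if g > 0:
        return (kBT / g) * np.log(
            np.exp(g * F0 / kBT) + threshold * g * r / (k0 * kBT)
        )
    return F0 + threshold * r / k0


def simulate_trace(
    pathway: UnfoldingPathway,
    protocol: PullingProtocol,
    seed: int | None = None,
    trace_id: str = "trace-000",
    rng: np.random.Generator | None = None,
) -> PullingTrace:
    """Simulate one constant-loading-rate pull along a pathway.

    The force ramps at the nominal loading rate; at each transition the
    unfolded contour length grows by the state's increment, the extension
    jumps by the WLC value at the rupture force, and the force drops by
    ``effective_stiffness * jump`` before the ramp resumes. Transition
    forces are sampled exactly (closed-form cumulative hazard against
    exponential waiting thresholds). Gaussian noise is added to both
    recorded channels; the ground-truth event log keeps the exact values.

    If the ramp reaches ``max_force`` with transitions still untriggered,
    the trace is returned with ``truncated=True`` rather than raising.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    r = protocol.loading_rate

    # --- event schedule (exact, segment by segment) ---
    seg_t0 = [0.0]  # segment start times
    seg_f0 = [0.0]  # force at segment start
    seg_lc = [0.0]  # unfolded contour length during segment
    events: list[GroundTruthEvent] = []
    truncated = False
    t0, f0, lc = 0.0, 0.0, 0.0
    for state in pathway.states:
        if state.kinetics.k0 == 0:
            truncated = True
            break
        threshold = rng.exponential()
        fc = _transition_force(f0, state.kinetics, r, threshold)
        if fc >= protocol.max_force:
            truncated = True
            break
        tc = t0 + (fc - f0) / r
        xi = wlc_fractional_extension(fc, pathway.unfolded_Lp, pathway.kBT)
        jump = state.delta_Lc * xi
        drop = protocol.effective_stiffness * jump
        events.append(GroundTruthEvent(time=tc, force=fc, delta_Lc=state.delta_Lc))
        lc += state.delta_Lc
        t0, f0 = tc, max(fc - drop, 0.0)
        seg_t0.append(t0)
        seg_f0.append(f0)
        seg_lc.append(lc)

    t_end = t0 + (protocol.max_force - f0) / r

    # --- sampled channels ---
    times = np.arange(0.0, t_end, protocol.sampling_interval)
    seg_idx = np.searchsorted(np.asarray(seg_t0[1:]), times, side="right")
    f0_arr = np.asarray(seg_f0)[seg_idx]
    t0_arr = np.asarray(seg_t0)[seg_idx]
    lc_arr = np.asarray(seg_lc)[seg_idx]
    force = f0_arr + r * (times - t0_arr)
    extension = pathway.folded_Lc * wlc_fractional_extension(
        force, pathway.folded_Lp, pathway.kBT
    ) + lc_arr * wlc_fractional_extension(force, pathway.unfolded_Lp, pathway.kBT)

    if protocol.noise_sd_force > 0:
        force = force + rng.normal(0.0, protocol.noise_sd_force, size=force.shape)
    if protocol.noise_sd_extension > 0:
        extension = extension + rng.normal(
            0.0, protocol.noise_sd_extension, size=extension.shape
        )

    return PullingTrace(
        trace_id=trace_id,
        time=times,
        force=force,
        extension=extension,
        loading_rate=r,
        ground_truth_events=tuple(events),
        truncated=truncated,
        protocol=protocol,
    )


@dataclass(frozen=True)
class ExperimentResult:
    """A batch of simulated traces across loading rates, with ground truth."""

    traces: tuple[PullingTrace, ...]
    pathway: UnfoldingPathway
    loading_rates: tuple[float, ...]
    seed: int | None = None

    def traces_at(self, loading_rate: float) -> list[PullingTrace]:
        return [t for t in self.traces if t.loading_rate == loading_rate]


def simulate_experiment(
    pathway: UnfoldingPathway,
    loading_rates,
    n_traces_per_rate: int,
    seed: int | None = None,
    protocol: PullingProtocol | None = None,
) -> ExperimentResult:
    """Simulate a full pulling campaign: ``n_traces_per_rate`` pulls at each
    loading rate, each trace with an independent child seed spawned from
    ``seed`` so the whole experiment is reproducible.
    """
    rates = tuple(float(r) for r in np.atleast_1d(loading_rates))
    if len(rates) < 1:
        raise InputError("need at least one loading rate")
    if n_traces_per_rate < 0:
        raise InputError("n_traces_per_rate must be >= 0")
    if protocol is None:
        protocol = PullingProtocol()

    n_total = len(rates) * int(n_traces_per_rate)
    children = np.random.SeedSequence(seed).spawn(n_total) if n_total else []
    traces: list[PullingTrace] = []
    k = 0
    for rate in rates:
        proto = dataclasses.replace(protocol, loading_rate=rate)
        for i in range(int(n_traces_per_rate)):
            rng = np.random.default_rng(children[k])
            traces.append(
                simulate_trace(
                    pathway, proto, rng=rng, trace_id=f"r{rate:g}-{i:04d}"
                )
            )
            k += 1
    return ExperimentResult(
        traces=tuple(traces), pathway=pathway, loading_rates=rates, seed=seed
    )
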
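"""End-to-end analysis: simulate -> detect -> histogram -> fit -> report.

``run_pipeline`` executes the full chain for every configured condition:
simulate a pulling campaign at the condition's ground truth, detect
unfolding events, reduce them to per-loading-rate most-probable forces,
fit Bell-Evans kinetics to the force spectrum and a worm-like chain to the
(rupture force, extension gain) cloud, and — when two or more conditions
are present — compute the stability-crossover force of each condition
against the first (reference) condition from the fitted kinetics.

Everything is deterministic given the configuration seed: the report of
two runs with identical configurations is byte-identical.
"""

from __future__ import annotations

import numpy as np

from . import __version__
from .config import RunConfig
from .errors import A2MechError
from .force_models import (
    BellEvansParams,
    crossover_force,
    fit_bell_evans,
    fit_wlc,
)
from .io import config_hash, write_json
from .pulling_simulator import (
    ExperimentResult,
    PullingProtocol,
    UnfoldingPathway,
    UnfoldingState,
    simulate_experiment,
)
from .trace_analysis import detect_unfolding_events, most_probable_force

__all__ = [
    "pathway_from_condition",
    "dynamic_force_spectrum",
    "analyze_pulling_experiment",
    "run_pipeline",
    "REPORT_SCHEMA_VERSION",
    "validate_report",
]

REPORT_SCHEMA_VERSION = 1

_REPORT_REQUIRED_KEYS = {"schema_version", "conditions", "provenance"}
_CONDITION_REQUIRED_KEYS = {
    "bell_evans",
    "wlc",
    "rate_points",
    "n_traces",
    "n_events",
}


def pathway_from_condition(cond, kBT: float) -> UnfoldingPathway:
    """Build the simulator pathway encoded by a condition configuration."""
    kinetics = cond.per_step_kinetics or tuple(
        (cond.k0, cond.gamma) for _ in cond.delta_Lc
    )
    states = tuple(
        UnfoldingState(dlc, BellEvansParams(k0, g, kBT))
        for dlc, (k0, g) in zip(cond.delta_Lc, kinetics)
    )
    return UnfoldingPathway(states=states, unfolded_Lp=cond.Lp, kBT=kBT)


def dynamic_force_spectrum(
    experiment: ExperimentResult,
    min_force_drop: float = 1.0,
    min_extension_gain: float = 5.0,
    bin_width: float = 1.0,
):
    """Detect events and reduce them to one (rate, F*, half-bin) point per
    loading rate plus the pooled event list.

    The loading rate attached to each spectrum point is the median of the
    per-event pre-rupture slope estimates in that group, i.e. it is measured
    from the data rather than copied from the protocol.
    """
    all_events = []
    points = []
    for rate in experiment.loading_rates:
        group_events = []
        for trace in experiment.traces_at(rate):
            group_events.extend(
                detect_unfolding_events(
                    trace,
                    min_force_drop=min_force_drop,
                    min_extension_gain=min_extension_gain,
                )
            )
        all_events.extend(group_events)
        if not group_events:
            continue
        fstar, half_bin = most_probable_force(group_events, bin_width=bin_width)
        measured_rate = float(np.median([e.loading_rate for e in group_events]))
        points.append(
            {
                "nominal_rate_pNs": float(rate),
                "loading_rate_pNs": measured_rate,
                "most_probable_force_pN": fstar,
                "half_bin_pN": half_bin,
                "n_events": len(group_events),
            }
        )
    return points, all_events


def analyze_pulling_experiment(
    experiment: ExperimentResult,
    min_force_drop: float = 1.0,
    min_extension_gain: float = 5.0,
    bin_width: float = 1.0,
    kBT: float | None = None,
) -> dict:
    """Full single-condition analysis of a pulling experiment.

    Returns a JSON-ready dict with the per-rate force spectrum, the fitted
    Bell-Evans kinetics, and the worm-like-chain fit to the pooled
    (rupture force, extension gain) points.
    """
    if kBT is None:
        kBT = experiment.pathway.kBT
    points, events = dynamic_force_spectrum(
        experiment,
        min_force_drop=min_force_drop,
        min_extension_gain=min_extension_gain,
        bin_width=bin_width,
    )
    if len(points) < 2:
        raise A2MechError(
            "fewer than two loading rates yielded events; cannot fit kinetics"
        )
    be_fit = fit_bell_evans(
        [p["loading_rate_pNs"] for p in points],
        [p["most_probable_force_pN"] for p in points],
        kBT=kBT,
    )
    # extension gains are measured at matched force, so their noise lives on
    # the extension channel: regress extension on force
    wlc_fit = fit_wlc(
        [e.rupture_force for e in events],
        [e.extension_gain for e in events],
        kBT=kBT,
        objective="extension",
    )
    return {
        "rate_points": points,
        "n_traces": len(experiment.traces),
        "n_events": len(events),
        "bell_evans": be_fit.to_dict(),
        "wlc": wlc_fit.to_dict(),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline for every condition in the configuration.

    Per-condition sub-seeds are spawned deterministically from the config
    seed. With two or more conditions the report carries a comparison block:
    the crossover force of each non-reference condition against the first
    condition, computed from the *fitted* kinetics.
    """
    protocol = PullingProtocol(
        loading_rate=config.loading_rates[0],
        sampling_interval=config.sampling_interval,
        max_force=config.max_force,
        noise_sd_force=config.noise_sd_force,
        noise_sd_extension=config.noise_sd_extension,
        effective_stiffness=config.effective_stiffness,
    )
    condition_seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.conditions)
    )

    report_conditions = {}
    fitted = {}
    for cond, sub_seed in zip(config.conditions, condition_seeds):
        pathway = pathway_from_condition(cond, config.kBT)
        experiment = simulate_experiment(
            pathway,
            config.loading_rates,
            config.n_traces_per_rate,
            seed=int(sub_seed),
            protocol=protocol,
        )
        try:
            analysis = analyze_pulling_experiment(
                experiment,
                min_force_drop=config.min_force_drop,
                min_extension_gain=config.min_extension_gain,
                bin_width=config.bin_width,
                kBT=config.kBT,
            )
        except A2MechError as exc:
            raise A2MechError(f"condition {cond.label!r}: {exc}") from exc
        analysis["ground_truth"] = {
            "k0_per_s": cond.k0,
            "gamma_nm": cond.gamma,
            "delta_Lc_nm": list(cond.delta_Lc),
            "Lp_nm": cond.Lp,
        }
        report_conditions[cond.label] = analysis
        fitted[cond.label] = BellEvansParams(
            k0=analysis["bell_evans"]["k0_per_s"],
            gamma=analysis["bell_evans"]["gamma_nm"],
            kBT=config.kBT,
        )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "conditions": report_conditions,
        "provenance": {
            "seed": config.seed,
            "config_sha256": config_hash(config.to_dict()),
            "package_version": __version__,
        },
    }

    if len(config.conditions) >= 2:
        reference = config.conditions[0].label
        comparison = {"reference": reference, "crossover_force_pN": {}}
        for label, params in fitted.items():
            if label == reference:
                continue
            try:
                fx = crossover_force(fitted[reference], params)
            except A2MechError:
                fx = None
            comparison["crossover_force_pN"][label] = fx
        report["comparison"] = comparison
    return report


def validate_report(report: dict) -> None:
    """Check a pipeline report against the published structure; raises
    ``A2MechError`` listing any missing keys."""
    missing = _REPORT_REQUIRED_KEYS - set(report)
    problems = [f"report missing keys {sorted(missing)}"] if missing else []
    for label, cond in report.get("conditions", {}).items():
        miss = _CONDITION_REQUIRED_KEYS - set(cond)
        if miss:
            problems.append(f"condition {label!r} missing keys {sorted(miss)}")
    if problems:
        raise A2MechError("; ".join(problems))


def write_report(report: dict, path) -> None:
    validate_report(report)
    write_json(report, path)
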
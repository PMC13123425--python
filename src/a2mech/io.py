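"""Readers and writers for the package's delimited-text formats.

Pulling traces travel as tab-separated tables (``trace_id``, ``time_s``,
``extension_nm``, ``force_pN``) with an optional JSON ground-truth sidecar;
titrations and kinetic traces as CSV. Fit results and reports are flat JSON
written canonically (sorted keys, fixed indentation) so identical analyses
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding_titration import TitrationSeries
from .enzyme_kinetics import KineticTrace
from .errors import SchemaError, ValidationError
from .pulling_simulator import GroundTruthEvent, PullingTrace

__all__ = [
    "TRACE_COLUMNS",
    "write_trace_table",
    "read_trace_table",
    "write_ground_truth",
    "read_ground_truth",
    "write_titration_csv",
    "read_titration_csv",
    "write_kinetics_csv",
    "read_kinetics_csv",
    "events_to_frame",
    "write_json",
    "config_hash",
]

TRACE_COLUMNS = ("trace_id", "time_s", "extension_nm", "force_pN")
TITRATION_COLUMNS = ("conc_M", "signal")
KINETICS_COLUMNS = ("time_s", "rfu")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def write_trace_table(traces, path) -> None:
    """Write traces to a tab-separated table (one row per sample)."""
    frames = [
        pd.DataFrame(
            {
                "trace_id": t.trace_id,
                "time_s": t.time,
                "extension_nm": t.extension,
                "force_pN": t.force,
            }
        )
        for t in traces
    ]
    # %.17g guarantees exact float round trips through the text format
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_trace_table(path) -> list[PullingTrace]:
    """Read a trace table written by :func:`write_trace_table`.

    Non-numeric rows are reported with their file line numbers; a trace
    whose time stamps are not strictly increasing raises a
    :class:`ValidationError` naming the trace. The nominal loading rate of
    each loaded trace is estimated by a global linear fit of force on time
    (the protocol is not stored in the table).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    numeric = df[["time_s", "extension_nm", "force_pN"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValidationError(f"{path}: malformed numeric rows at lines {lines}")
    df[["time_s", "extension_nm", "force_pN"]] = numeric

    traces = []
    for trace_id, group in df.groupby("trace_id", sort=False):
        t = group["time_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{path}: trace {trace_id!r} has non-monotone time stamps"
            )
        f = group["force_pN"].to_numpy()
        rate = float(np.polyfit(t, f, 1)[0]) if t.size > 1 else float("nan")
        traces.append(
            PullingTrace(
                trace_id=str(trace_id),
                time=t,
                force=f,
                extension=group["extension_nm"].to_numpy(),
                loading_rate=rate,
            )
        )
    return traces


def write_ground_truth(traces, path) -> None:
    """JSON sidecar with the exact simulated events of each trace."""
    doc = {
        "traces": {
            t.trace_id: {
                "loading_rate_pNs": t.loading_rate,
                "truncated": t.truncated,
                "events": [
                    {"time_s": e.time, "force_pN": e.force, "delta_Lc_nm": e.delta_Lc}
                    for e in t.ground_truth_events
                ],
            }
            for t in traces
        }
    }
    write_json(doc, path)


def read_ground_truth(path) -> dict[str, list[GroundTruthEvent]]:
    doc = json.loads(Path(path).read_text())
    return {
        trace_id: [
            GroundTruthEvent(
                time=e["time_s"], force=e["force_pN"], delta_Lc=e["delta_Lc_nm"]
            )
            for e in entry["events"]
        ]
        for trace_id, entry in doc["traces"].items()
    }


def write_titration_csv(series_list, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "conc_M": s.concentrations,
                "signal": s.signal,
                "replicate": s.replicate_id,
                "target": s.target_label,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_titration_csv(path) -> list[TitrationSeries]:
    df = pd.read_csv(path)
    _require_columns(df, TITRATION_COLUMNS, path)
    if "replicate" not in df.columns:
        df["replicate"] = "rep-1"
    if "target" not in df.columns:
        df["target"] = ""
    return [
        TitrationSeries(
            concentrations=g["conc_M"].to_numpy(),
            signal=g["signal"].to_numpy(),
            replicate_id=str(rep),
            target_label=str(g["target"].iloc[0]),
        )
        for rep, g in df.groupby("replicate", sort=False)
    ]


def write_kinetics_csv(traces, path) -> None:
    frames = [
        pd.DataFrame(
            {"time_s": t.time, "rfu": t.fluorescence, "condition": t.condition}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_kinetics_csv(path) -> list[KineticTrace]:
    df = pd.read_csv(path)
    _require_columns(df, KINETICS_COLUMNS, path)
    if "condition" not in df.columns:
        df["condition"] = ""
    return [
        KineticTrace(
            time=g["time_s"].to_numpy(),
            fluorescence=g["rfu"].to_numpy(),
            condition=str(cond),
        )
        for cond, g in df.groupby("condition", sort=False)
    ]


def events_to_frame(events) -> pd.DataFrame:
    """Detected unfolding events as a tidy table."""
    return pd.DataFrame(
        {
            "trace_id": [e.trace_id for e in events],
            "time_s": [e.time for e in events],
            "rupture_force_pN": [e.rupture_force for e in events],
            "force_drop_pN": [e.force_drop for e in events],
            "extension_gain_nm": [e.extension_gain for e in events],
            "loading_rate_pNs": [e.loading_rate for e in events],
        }
    )


def write_json(obj, path) -> None:
    """Canonical JSON: sorted keys, two-space indent, trailing newline."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_hash(config_dict: dict) -> str:
    """Stable SHA-256 of a configuration mapping, for report provenance."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()
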
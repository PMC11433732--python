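"""File I/O for concentration-time tables, run manifests and figures.

The canonical table format is UTF-8 CSV with '.' decimal and fixed header::

    subject,group,analyte,time_h,conc_ug_L,censored,dose_mg,lloq_ug_L

Units are fixed by the header contract; analytes outside the monitored set
are rejected.  Reading then writing a table is byte-stable for canonical
formatting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engine import SimulationResult
from .metrics import CtSeries, PKSummary
from .parameters import ANALYTES

__all__ = [
    "CT_COLUMNS",
    "read_ct_table",
    "write_ct_table",
    "series_from_frame",
    "frame_from_series",
    "result_to_frame",
    "write_manifest",
    "write_summaries",
    "plot_profiles",
]

CT_COLUMNS = (
    "subject", "group", "analyte", "time_h", "conc_ug_L",
    "censored", "dose_mg", "lloq_ug_L",
)


def read_ct_table(path: str | Path) -> list[CtSeries]:
    """Read a concentration-time CSV into per-(subject, analyte) series.

    Raises a schema error naming the offending column or row; an empty file
    with a valid header yields an empty list.
    """
    df = pd.read_csv(path, dtype={"subject": str, "group": str, "analyte": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    bad = df.loc[~df["analyte"].isin(ANALYTES)]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(
            f"row {row}: unknown analyte {bad['analyte'].iloc[0]!r} "
            f"(expected one of {', '.join(ANALYTES)})"
        )
    return series_from_frame(df)


def series_from_frame(df: pd.DataFrame) -> list[CtSeries]:
    out: list[CtSeries] = []
    for (subject, analyte), grp in df.groupby(["subject", "analyte"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            CtSeries(
                analyte=str(analyte),
                t=grp["time_h"].to_numpy(float),
                conc=grp["conc_ug_L"].to_numpy(float),
                dose_mg=float(grp["dose_mg"].iloc[0]),
                group=str(grp["group"].iloc[0]),
                subject=str(subject),
                lloq=float(grp["lloq_ug_L"].iloc[0]),
                censored=grp["censored"].to_numpy(bool),
            )
        )
    return out


def frame_from_series(series: Iterable[CtSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for i in range(s.t.size):
            rows.append(
                (s.subject, s.group, s.analyte, s.t[i], s.conc[i],
                 bool(s.censored[i]), s.dose_mg, s.lloq)
            )
    df = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    # canonical row order makes write(read(x)) byte-stable
    return df.sort_values(["subject", "analyte", "time_h"],
                          kind="stable").reset_index(drop=True)


def write_ct_table(series: Iterable[CtSeries], path: str | Path) -> None:
    frame_from_series(series).to_csv(path, index=False, float_format="%.10g")


def result_to_frame(result: SimulationResult, subject: str = "model") -> pd.DataFrame:
    """Flatten a simulation result into the canonical table layout."""
    rows = []
    for analyte in ANALYTES:
        c = result.conc[analyte]
        for t, v in zip(result.t, c):
            rows.append((subject, result.group, analyte, t, v, False,
                         result.dose_mg, 0.0))
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    payload = {"version": __version__, **manifest}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_summaries(summaries: Sequence[PKSummary], path: str | Path) -> None:
    """Delimited summary table (group, analyte, AUC, window half-lives)."""
    df = pd.DataFrame(
        [
            {
                "group": s.group,
                "analyte": s.analyte,
                "auc_ug_h_L": s.auc,
                "auc_t0_h": s.auc_interval[0],
                "auc_t1_h": s.auc_interval[1],
                "c_max_ug_L": s.c_max,
                "t_max_h": s.t_max,
                "t_half_12_24_h": s.t_half_12_24,
                "t_half_24_36_h": s.t_half_24_36,
            }
            for s in summaries
        ]
    )
    df.to_csv(path, index=False, float_format="%.6g")


def plot_profiles(
    result: SimulationResult,
    path: str | Path,
    observed: Sequence[CtSeries] = (),
    log_scale: bool = True,
) -> None:
    """Static overlay figure: model curves, optional observed points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(ANALYTES), figsize=(4 * len(ANALYTES), 3.2),
                             sharex=True)
    obs_by_analyte: dict[str, list[CtSeries]] = {}
    for s in observed:
        obs_by_analyte.setdefault(s.analyte, []).append(s)
    for ax, analyte in zip(np.atleast_1d(axes), ANALYTES):
        ax.plot(result.t, result.conc[analyte], "k-", lw=1.2, label="model")
        for s in obs_by_analyte.get(analyte, ()):
            m = s.usable()
            ax.plot(s.t[m], s.conc[m], "o", ms=3, alpha=0.6)
        if log_scale:
            ax.set_yscale("log")
        ax.set_title(analyte)
        ax.set_xlabel("time (h)")
    np.atleast_1d(axes)[0].set_ylabel("plasma conc (ug/L)")
    fig.suptitle(f"{result.group}, {result.dose_mg:g} mg")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
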
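"""Serialization: long-format CSV/TSV writers and their inverse readers.

Every writer has a reader that reconstructs an object comparing equal to
the source (tested round-trip).  Long format (one value per row with full
coordinates) keeps the files language-agnostic and diff-friendly.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .meanfield import GridField, VolterraSolution
from .simulate import EventRecord, Trajectory

__all__ = [
    "write_events_tsv", "read_events_tsv",
    "write_field_csv", "read_field_csv",
    "write_volterra_csv", "read_volterra_csv",
    "write_series_csv", "write_meta",
]


def write_events_tsv(events: Iterable[EventRecord], path) -> None:
    rows = [{
        "time": e.time, "kind": e.kind, "parent_tob": e.parent_tob,
        "child_tobs": ";".join(f"{c:.17g}" for c in e.child_tobs),
        "n_before": e.n_before,
    } for e in events]
    pd.DataFrame(rows, columns=["time", "kind", "parent_tob", "child_tobs",
                                "n_before"]).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> List[EventRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        childs = tuple(float(c) for c in str(r["child_tobs"]).split(";")
                       if c != "")
        out.append(EventRecord(float(r["time"]), str(r["kind"]),
                               float(r["parent_tob"]), childs,
                               int(r["n_before"])))
    return out


def write_field_csv(field: GridField, path) -> None:
    df = field.to_frame()
    df.attrs = {}
    df.to_csv(path, index=False)


def read_field_csv(path) -> GridField:
    df = pd.read_csv(path)
    axis_name = df.columns[0]
    a = np.unique(df[axis_name].to_numpy())
    t = np.unique(df["t"].to_numpy())
    piv = df.pivot(index=axis_name, columns="t", values="value")
    return GridField(a=a, t=t, values=piv.to_numpy(), convention=axis_name)


def write_volterra_csv(sol: VolterraSolution, path) -> None:
    pd.DataFrame({"t": sol.t, "B": sol.B}).to_csv(path, index=False)


def read_volterra_csv(path) -> VolterraSolution:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    return VolterraSolution(t=t, B=df["B"].to_numpy(), h=float(t[1] - t[0]))


def write_series_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=True)


def write_meta(path, config: dict, seeds, extra: dict | None = None) -> None:
    meta = {
        "config": config,
        "seeds": seeds,
        "written_at_unix": time.time(),
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
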
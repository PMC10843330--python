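"""Delimited-text interchange formats.

Traces are CSV with a '#'-prefixed metadata block (delta_t_s, orientation,
genotype, specimen_id) followed by a mandatory header row
``time_s,displacement_um``.  Genotype tables are plain CSV with columns
genotype, specimen_id, value.  Decimal separator is '.'.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .groupstats import GenotypeSample
from .rheology import DisplacementTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_genotype_table",
    "read_genotype_table",
]


def write_trace(trace: DisplacementTrace, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# delta_t_s = {trace.delta_t}",
        f"# orientation = {trace.orientation}",
        f"# genotype = {trace.genotype}",
        f"# specimen_id = {trace.specimen_id}",
        "time_s,displacement_um",
    ]
    for t, d in zip(trace.times, trace.displacements):
        lines.append(f"{float(t)!r},{float(d)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> DisplacementTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    header = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("#").split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            if "time_s" not in header or "displacement_um" not in header:
                raise ValueError(
                    f"{path}: header must contain time_s and displacement_um, got {header}"
                )
            continue
        rows.append([float(x) for x in line.split(",")])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    it, id_ = header.index("time_s"), header.index("displacement_um")
    return DisplacementTrace(
        times=arr[:, it],
        displacements=arr[:, id_],
        delta_t=float(meta.get("delta_t_s", 0.65)),
        orientation=meta.get("orientation", "PD"),
        genotype=meta.get("genotype", ""),
        specimen_id=meta.get("specimen_id", ""),
    )


def write_genotype_table(pools: list[GenotypeSample], path: str | Path) -> None:
    rows = []
    for g in pools:
        for i, v in enumerate(g.values):
            rows.append({"genotype": g.genotype, "specimen_id": f"{g.genotype}_{i:03d}", "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotype_table(path: str | Path) -> list[GenotypeSample]:
    df = pd.read_csv(path)
    missing = {"genotype", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GenotypeSample(genotype=str(g), values=sub["value"].to_numpy())
        for g, sub in df.groupby("genotype", sort=False)
    ]
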
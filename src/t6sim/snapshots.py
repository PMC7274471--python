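"""Snapshot and trajectory persistence: lossless per-cell CSV tables,
event logs, and optional legacy-ASCII VTK export for 3D visualization."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import Cell, CellState, Event, Genotype, Population, SimClock, Trajectory

__all__ = ["write_snapshot", "read_snapshot", "write_events", "read_events",
           "write_trajectory", "read_trajectory", "write_vtk"]

_COLUMNS = ["id", "genotype", "state", "x", "y", "z", "ax", "ay", "az",
            "length", "radius", "volume", "growth_rate", "birth_volume",
            "div_threshold", "tallies", "death_time", "lysis_delay"]


def _serialize_tallies(tallies: dict) -> str:
    return ";".join(f"{gid}:{cnt}" for gid, cnt in sorted(tallies.items())) or ""


def _parse_tallies(text, row: int) -> dict:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return {}
    out = {}
    try:
        for part in str(text).split(";"):
            gid, cnt = part.split(":")
            out[int(gid)] = int(cnt)
    except ValueError as exc:
        raise ValueError(f"snapshot row {row}: malformed tallies {text!r}") from exc
    return out


def write_snapshot(pop: Population, path: str | Path):
    """One row per cell, full float precision; lossless round trip."""
    rows = []
    for i in range(pop.n):
        c = pop.cell(i)
        rows.append([c.id, c.genotype_id, c.state.name, *c.center, *c.axis,
                     c.length, c.radius, c.volume, c.growth_rate,
                     c.birth_volume, c.div_threshold,
                     _serialize_tallies(c.hit_tallies), c.death_time,
                     c.lysis_delay])
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_snapshot(path: str | Path, genotypes: list[Genotype],
                  clock: SimClock | None = None, rng_seed: int = 0) -> Population:
    # round_trip parsing: pandas' fast float path can be off by one ulp
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot {path}: missing column(s) {sorted(missing)}")
    cells = []
    for row, rec in enumerate(df.itertuples(index=False)):
        try:
            state = CellState[rec.state]
        except KeyError:
            raise ValueError(f"snapshot row {row}: unknown state {rec.state!r}")
        cells.append(Cell(
            id=int(rec.id), genotype_id=int(rec.genotype),
            center=np.array([rec.x, rec.y, rec.z]),
            axis=np.array([rec.ax, rec.ay, rec.az]),
            length=float(rec.length), radius=float(rec.radius),
            growth_rate=float(rec.growth_rate), state=state,
            birth_volume=float(rec.birth_volume),
            div_threshold=float(rec.div_threshold),
            hit_tallies=_parse_tallies(rec.tallies, row),
            death_time=float(rec.death_time), lysis_delay=float(rec.lysis_delay)))
    return Population.from_cells(cells, genotypes, clock=clock, rng_seed=rng_seed)


def write_events(trajectory: Trajectory, path: str | Path):
    trajectory.events_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path)
    return [Event(float(r.t), str(r.kind), int(r.cell_id), int(r.genotype_id),
                  float(r.aux)) for r in df.itertuples(index=False)]


def write_trajectory(trajectory: Trajectory, outdir: str | Path):
    """Directory layout: genotypes.json, events.csv, snapshots/tNNNN.csv."""
    outdir = Path(outdir)
    (outdir / "snapshots").mkdir(parents=True, exist_ok=True)
    genos = [vars(g) for g in trajectory.genotypes]
    (outdir / "genotypes.json").write_text(json.dumps(genos, indent=1))
    write_events(trajectory, outdir / "events.csv")
    index = []
    for k, (t, pop) in enumerate(trajectory.snapshots):
        name = f"snapshots/t{k:05d}.csv"
        write_snapshot(pop, outdir / name)
        index.append({"file": name, "t": t})
    (outdir / "snapshots.json").write_text(json.dumps(index, indent=1))


def read_trajectory(outdir: str | Path) -> Trajectory:
    outdir = Path(outdir)
    genos = [Genotype(**g) for g in json.loads((outdir / "genotypes.json").read_text())]
    traj = Trajectory(genos)
    traj.events = read_events(outdir / "events.csv")
    for item in json.loads((outdir / "snapshots.json").read_text()):
        pop = read_snapshot(outdir / item["file"], genos,
                            clock=SimClock(t=item["t"]))
        traj.snapshots.append((float(item["t"]), pop))
    return traj


def write_vtk(pop: Population, path: str | Path):
    """Capsule glyphs as legacy-ASCII VTK polylines with radius/state data."""
    pa, pb = pop.endpoints()
    n = pop.n
    lines = [
        "# vtk DataFile Version 3.0",
        "t6sim cell snapshot", "ASCII", "DATASET POLYDATA",
        f"POINTS {2 * n} float",
    ]
    for k in range(n):
        lines.append(" ".join(f"{v:.6f}" for v in pa[k]))
        lines.append(" ".join(f"{v:.6f}" for v in pb[k]))
    lines.append(f"LINES {n} {3 * n}")
    for k in range(n):
        lines.append(f"2 {2 * k} {2 * k + 1}")
    lines.append(f"CELL_DATA {n}")
    lines.append("SCALARS radius float 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{r:.6f}" for r in pop.radius)
    lines.append("SCALARS genotype int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(g)) for g in pop.genotype_ids)
    lines.append("SCALARS state int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(s)) for s in pop.state)
    Path(path).write_text("\n".join(lines) + "\n")
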
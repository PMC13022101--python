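"""Persist metric matrices as CSV tables and B-factor-annotated PDB snapshots."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RmsxError
from .metrics import MetricMatrix
from .structure_io import TrajectorySystem, write_pdb_frame

__all__ = [
    "SnapshotSet",
    "write_rmsx_csv",
    "read_rmsx_csv",
    "write_bfactor_snapshots",
    "read_snapshot_remark",
]

FRAME_RULES = ("first", "middle", "last")

_REMARK_RE = re.compile(
    r"REMARK 100 FLIPBOOK kind=(?P<kind>\w+) vmin=(?P<vmin>[-0-9.eE+]+) "
    r"vmax=(?P<vmax>[-0-9.eE+]+) palette=(?P<palette>\w+)"
)


@dataclass(frozen=True)
class SnapshotSet:
    """Ordered per-slice PDB snapshots sharing one value range and palette."""

    paths: tuple[Path, ...]
    vmin: float
    vmax: float
    palette: str
    kind: str
    frame_rule: str

    def __post_init__(self) -> None:
        if not self.vmin <= self.vmax:
            raise RmsxError(f"invalid value range ({self.vmin}, {self.vmax})")


def _value_format(kind: str) -> str:
    # lDDT is bounded in [0,1]: fixed 4 decimals; Å metrics: 6 significant digits
    return "%.4f" if kind == "lddt" else "%.6g"


def write_rmsx_csv(matrix: MetricMatrix, path: str | Path) -> Path:
    """Write a metric matrix as a long-format CSV.

    One row per (residue, time bin) with header
    ``chain_id,residue_id,residue_name,slice_index,slice_start_ns,slice_end_ns,value``.
    """
    if matrix.values.size == 0:
        raise RmsxError("refusing to write an empty metric matrix")
    path = Path(path)
    edges = np.asarray(matrix.time_edges_ns)
    rows = []
    for i, (chain, resid, resname) in enumerate(matrix.residue_labels):
        for k in range(matrix.n_bins):
            rows.append(
                (chain, resid, resname, k, edges[k], edges[k + 1], matrix.values[i, k])
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "chain_id",
            "residue_id",
            "residue_name",
            "slice_index",
            "slice_start_ns",
            "slice_end_ns",
            "value",
        ],
    )
    frame.to_csv(path, index=False, float_format=_value_format(matrix.kind))
    return path


def read_rmsx_csv(path: str | Path, kind: str = "rmsx") -> MetricMatrix:
    """Reconstruct a metric matrix from :func:`write_rmsx_csv` output."""
    table = pd.read_csv(path)
    labels: list[tuple[str, int, str]] = []
    seen = set()
    for chain, resid, resname in zip(
        table.chain_id, table.residue_id, table.residue_name
    ):
        key = (str(chain), int(resid))
        if key not in seen:
            seen.add(key)
            labels.append((str(chain), int(resid), str(resname)))
    n_bins = int(table.slice_index.max()) + 1
    values = np.full((len(labels), n_bins), np.nan)
    index = {(c, r): i for i, (c, r, _) in enumerate(labels)}
    for row in table.itertuples(index=False):
        values[index[(str(row.chain_id), int(row.residue_id))], int(row.slice_index)] = (
            row.value
        )
    starts = table.drop_duplicates("slice_index").sort_values("slice_index")
    edges = np.append(starts.slice_start_ns.to_numpy(), starts.slice_end_ns.iloc[-1])
    return MetricMatrix(
        kind=kind, values=values, residue_labels=labels, time_edges_ns=edges
    )


def representative_frame(bounds: tuple[int, int], rule: str) -> int:
    lo, hi = bounds
    if rule == "first":
        return lo
    if rule == "middle":
        return lo + (hi - lo) // 2
    if rule == "last":
        return hi - 1
    raise RmsxError(f"unknown frame rule {rule!r}; use one of {FRAME_RULES}")


def default_range(matrix: MetricMatrix) -> tuple[float, float]:
    """Shared palette range: (0, max) for Å metrics, (0, 1) for lDDT."""
    if matrix.kind == "lddt":
        return 0.0, 1.0
    return 0.0, float(np.nanmax(matrix.values))


def write_bfactor_snapshots(
    system: TrajectorySystem,
    matrix: MetricMatrix,
    out_dir: str | Path,
    frame_rule: str = "middle",
    palette: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> SnapshotSet:
    """Write one B-factor-annotated PDB per matrix column.

    Snapshot *k* is the representative frame of bin *k* with the column-*k*
    values broadcast to each residue's atoms as B-factors. Every snapshot
    carries an identical ``REMARK 100 FLIPBOOK`` line recording the metric
    kind, the shared (vmin, vmax) range, and the palette, so downstream
    viewer scripts reproduce a consistent scale.
    """
    if matrix.plan is None and matrix.frame_indices is None:
        raise RmsxError("matrix carries no frame mapping; cannot pick snapshots")
    if frame_rule not in FRAME_RULES:
        raise RmsxError(f"unknown frame rule {frame_rule!r}; use one of {FRAME_RULES}")
    d_vmin, d_vmax = default_range(matrix)
    vmin = d_vmin if vmin is None else float(vmin)
    vmax = d_vmax if vmax is None else float(vmax)
    finite = matrix.values[np.isfinite(matrix.values)]
    if finite.size and (vmin > finite.min() or vmax < finite.max()):
        raise RmsxError(
            f"range ({vmin}, {vmax}) does not cover matrix values "
            f"[{finite.min():.4g}, {finite.max():.4g}]"
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    remark = (
        f"100 FLIPBOOK kind={matrix.kind} vmin={vmin:.6g} vmax={vmax:.6g} "
        f"palette={palette}"
    )
    paths: list[Path] = []
    pad = max(3, len(str(matrix.n_bins - 1)))
    for k in range(matrix.n_bins):
        if matrix.plan is not None:
            frame = representative_frame(matrix.plan.slice_bounds[k], frame_rule)
        else:
            frame = int(matrix.frame_indices[k])
        values = {
            (chain, resid): (0.0 if not np.isfinite(v) else float(v))
            for (chain, resid, _), v in zip(matrix.residue_labels, matrix.values[:, k])
        }
        path = out_dir / f"slice_{k:0{pad}d}.pdb"
        write_pdb_frame(system, frame, values, path, remarks=[remark])
        paths.append(path)
    return SnapshotSet(
        paths=tuple(paths),
        vmin=vmin,
        vmax=vmax,
        palette=palette,
        kind=matrix.kind,
        frame_rule=frame_rule,
    )


def read_snapshot_remark(path: str | Path) -> dict:
    """Parse the FLIPBOOK remark of a snapshot; raise if absent."""
    for line in Path(path).read_text().splitlines():
        match = _REMARK_RE.match(line)
        if match:
            return {
                "kind": match["kind"],
                "vmin": float(match["vmin"]),
                "vmax": float(match["vmax"]),
                "palette": match["palette"],
            }
        if line.startswith("ATOM"):
            break
    raise RmsxError(
        f"{path} has no FLIPBOOK remark; regenerate snapshots with "
        "write_bfactor_snapshots"
    )
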
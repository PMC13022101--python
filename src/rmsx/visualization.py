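"""Heatmap/triple-plot rendering and viewer-script generation.

The color tables are packaged as 256-entry RGB CSV files so that the
heatmap PNG, the ChimeraX command script, and the VMD Tcl script all use
bit-identical palette stops. Viewer scripts are generated, never
executed, by this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import RmsxError
from .exporters import SnapshotSet, read_snapshot_remark
from .metrics import MetricMatrix
from .superposition import RmsdSeries

__all__ = [
    "PALETTES",
    "FlipbookSpec",
    "get_palette",
    "palette_stops",
    "heatmap_array",
    "render_heatmap",
    "render_triple_plot",
    "build_flipbook_spec",
    "generate_chimerax_script",
    "generate_vmd_script",
]

PALETTES = (
    "viridis",
    "magma",
    "plasma",
    "inferno",
    "cividis",
    "mako",
    "rocket",
    "turbo",
)

STOP_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)

_palette_cache: dict[str, np.ndarray] = {}


def get_palette(name: str) -> np.ndarray:
    """Packaged 256x3 uint8 RGB lookup table for a palette name."""
    if name not in PALETTES:
        raise RmsxError(
            f"unknown palette {name!r}; allowed: {', '.join(PALETTES)}"
        )
    if name not in _palette_cache:
        ref = resources.files("rmsx").joinpath(f"data/palettes/{name}.csv")
        table = np.loadtxt(str(ref), delimiter=",", skiprows=1, dtype=int)
        if table.shape != (256, 3):
            raise RmsxError(f"corrupt palette table for {name}: shape {table.shape}")
        _palette_cache[name] = table.astype(np.uint8)
    return _palette_cache[name]


def palette_stops(name: str, fractions=STOP_FRACTIONS) -> list[str]:
    """Hex colors of the palette at the given fractional positions."""
    table = get_palette(name)
    stops = []
    for f in fractions:
        r, g, b = table[int(round(f * 255))]
        stops.append(f"#{r:02x}{g:02x}{b:02x}")
    return stops


@dataclass(frozen=True)
class FlipbookSpec:
    """Everything a viewer script needs: ordered snapshots, shared scale, layout."""

    snapshot_paths: tuple[Path, ...]
    palette: str
    vmin: float
    vmax: float
    kind: str = "rmsx"
    spacing: float = 50.0
    snapshots_per_row: int = 0  # 0 = single row
    r_min: float = 0.2
    r_max: float = 1.5
    viewer: str = "chimerax"

    def __post_init__(self) -> None:
        if self.palette not in PALETTES:
            raise RmsxError(
                f"unknown palette {self.palette!r}; allowed: {', '.join(PALETTES)}"
            )
        if not self.vmin < self.vmax:
            raise RmsxError(f"need vmin < vmax, got ({self.vmin}, {self.vmax})")
        if not self.r_min < self.r_max:
            raise RmsxError(f"need r_min < r_max, got ({self.r_min}, {self.r_max})")
        if self.viewer not in ("chimerax", "vmd"):
            raise RmsxError(f"unknown viewer {self.viewer!r}; use chimerax or vmd")
        if not self.snapshot_paths:
            raise RmsxError("flipbook needs at least one snapshot")
        for p in self.snapshot_paths:
            if not Path(p).exists():
                raise RmsxError(f"snapshot file missing: {p}")


def _normalize(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    span = vmax - vmin if vmax > vmin else 1.0
    return np.clip((values - vmin) / span, 0.0, 1.0)


def heatmap_array(
    matrix: MetricMatrix,
    palette: str = "viridis",
    interpolate: bool = False,
    vmin: float | None = None,
    vmax: float | None = None,
    upsample: int = 8,
    nan_rgb: tuple[int, int, int] = (128, 128, 128),
) -> np.ndarray:
    """RGB image array of the matrix (rows = residues ascending upward).

    Interpolation linearly upsamples along the time axis only; values at
    original bin centers are preserved exactly. NaN cells (undefined lDDT)
    render in a distinct flat gray.
    """
    table = get_palette(palette)
    values = matrix.values
    if interpolate and matrix.n_bins > 1:
        x = np.arange(matrix.n_bins, dtype=float)
        xi = np.linspace(0, matrix.n_bins - 1, (matrix.n_bins - 1) * upsample + 1)
        values = np.stack([np.interp(xi, x, row) for row in values])
    if vmin is None or vmax is None:
        finite = matrix.values[np.isfinite(matrix.values)]
        lo = 0.0 if matrix.kind in ("rmsx", "shift") else 0.0
        hi = 1.0 if matrix.kind == "lddt" else float(finite.max()) if finite.size else 1.0
        vmin = lo if vmin is None else vmin
        vmax = hi if vmax is None else vmax
    nan_mask = ~np.isfinite(values)
    norm = _normalize(np.nan_to_num(values, nan=0.0), vmin, vmax)
    img = table[np.round(norm * 255).astype(int)]
    img[nan_mask] = nan_rgb
    # flip so residue index ascends bottom-to-top in image row order
    return img[::-1]


def render_heatmap(
    matrix: MetricMatrix,
    palette: str = "viridis",
    interpolate: bool = False,
    path: str | Path = "rmsx_heatmap.png",
    vmin: float | None = None,
    vmax: float | None = None,
    title: str | None = None,
) -> Path:
    """Render the residues x time heatmap to PNG.

    Time in ns on the x-axis, residue index ascending bottom-to-top on the
    y-axis, colorbar labeled in Å (unitless for lDDT) spanning the shared
    range.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap, Normalize

    if vmin is None or vmax is None:
        finite = matrix.values[np.isfinite(matrix.values)]
        vmin = 0.0 if vmin is None else vmin
        if vmax is None:
            vmax = 1.0 if matrix.kind == "lddt" else float(finite.max() or 1.0)
    img = heatmap_array(matrix, palette, interpolate, vmin, vmax)
    resids = [resid for _, resid, _ in matrix.residue_labels]
    extent = (
        float(matrix.time_edges_ns[0]),
        float(matrix.time_edges_ns[-1]),
        min(resids) - 0.5,
        max(resids) + 0.5,
    )
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.imshow(img, aspect="auto", extent=extent, origin="upper",
              interpolation="nearest")
    ax.set_xlabel("Time (ns)")
    ax.set_ylabel("Residue")
    if title:
        ax.set_title(title)
    cmap = ListedColormap(get_palette(palette) / 255.0)
    mappable = plt.cm.ScalarMappable(norm=Normalize(vmin, vmax), cmap=cmap)
    label = "lDDT" if matrix.kind == "lddt" else "Displacement (Å)"
    fig.colorbar(mappable, ax=ax, label=label)
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_triple_plot(
    rmsd: RmsdSeries,
    matrix: MetricMatrix,
    rmsf_profile: np.ndarray,
    path: str | Path = "triple_plot.png",
    palette: str = "viridis",
    dt_ps: float | None = None,
) -> Path:
    """Composite figure: RMSD on top, heatmap center, RMSF profile right.

    The RMSD panel shares the heatmap's time axis; the RMSF panel shares
    the residue axis (displacement on x, residue index on y).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap, Normalize

    rmsf_profile = np.asarray(rmsf_profile, dtype=float)
    if rmsf_profile.shape != (matrix.n_residues,):
        raise RmsxError(
            f"residue-axis mismatch: RMSF profile has {rmsf_profile.shape[0]} "
            f"entries but the heatmap has {matrix.n_residues} residues"
        )
    if matrix.plan is not None:
        expected = matrix.plan.analyzed_frames
        if rmsd.values.shape[0] != expected:
            raise RmsxError(
                f"time-axis mismatch: RMSD series has {rmsd.values.shape[0]} "
                f"frames but the analyzed range holds {expected}"
            )
    if dt_ps is None:
        dt_ps = (matrix.plan.dt_ps if matrix.plan is not None else 1.0)

    t0, t1 = float(matrix.time_edges_ns[0]), float(matrix.time_edges_ns[-1])
    times = t0 + np.arange(rmsd.values.shape[0]) * dt_ps / 1000.0
    resids = [resid for _, resid, _ in matrix.residue_labels]
    vmin, vmax = 0.0, (1.0 if matrix.kind == "lddt" else float(np.nanmax(matrix.values)) or 1.0)
    img = heatmap_array(matrix, palette, False, vmin, vmax)

    fig = plt.figure(figsize=(9, 6))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[4, 1], height_ratios=[1, 3], hspace=0.08, wspace=0.06
    )
    ax_rmsd = fig.add_subplot(gs[0, 0])
    ax_heat = fig.add_subplot(gs[1, 0], sharex=ax_rmsd)
    ax_rmsf = fig.add_subplot(gs[1, 1], sharey=ax_heat)

    ax_rmsd.plot(times, rmsd.values, lw=0.8, color="black")
    ax_rmsd.set_ylabel("RMSD (Å)")
    ax_rmsd.tick_params(labelbottom=False)

    extent = (t0, t1, min(resids) - 0.5, max(resids) + 0.5)
    ax_heat.imshow(img, aspect="auto", extent=extent, origin="upper",
                   interpolation="nearest")
    ax_heat.set_xlim(t0, t1)
    ax_heat.set_xlabel("Time (ns)")
    ax_heat.set_ylabel("Residue")

    ax_rmsf.plot(rmsf_profile, resids, lw=1.0, color="black")
    ax_rmsf.set_xlabel("RMSF (Å)")
    ax_rmsf.tick_params(labelleft=False)

    cmap = ListedColormap(get_palette(palette) / 255.0)
    mappable = plt.cm.ScalarMappable(norm=Normalize(vmin, vmax), cmap=cmap)
    fig.colorbar(mappable, ax=[ax_heat, ax_rmsf], shrink=0.8,
                 label="lDDT" if matrix.kind == "lddt" else "Displacement (Å)")
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _structure_width(path: Path) -> float:
    xs = []
    for line in path.read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")):
            xs.append(float(line[30:38]))
    if not xs:
        return 30.0
    return max(max(xs) - min(xs), 1.0)


def build_flipbook_spec(
    snapshots: SnapshotSet | list | tuple,
    viewer: str = "chimerax",
    spacing: float | None = None,
    snapshots_per_row: int = 0,
    r_min: float = 0.2,
    r_max: float = 1.5,
    palette: str | None = None,
) -> FlipbookSpec:
    """Assemble a flipbook spec from snapshot files, enforcing one shared scale.

    The (vmin, vmax) range and palette are read from the snapshots' FLIPBOOK
    remarks; any disagreement across snapshots is an error. Default layout
    is a single row spaced at 1.5x the first structure's x-extent.
    """
    if isinstance(snapshots, SnapshotSet):
        paths = [Path(p) for p in snapshots.paths]
    else:
        paths = [Path(p) for p in snapshots]
    if not paths:
        raise RmsxError("flipbook needs at least one snapshot")
    remarks = [read_snapshot_remark(p) for p in paths]
    first = remarks[0]
    for p, rem in zip(paths[1:], remarks[1:]):
        if rem != first:
            raise RmsxError(
                f"snapshot {p} carries scale {rem} but the first snapshot has "
                f"{first}; all snapshots of a flipbook must share one scale"
            )
    if spacing is None:
        spacing = 1.5 * _structure_width(paths[0])
    return FlipbookSpec(
        snapshot_paths=tuple(paths),
        palette=palette or first["palette"],
        vmin=first["vmin"],
        vmax=first["vmax"],
        kind=first["kind"],
        spacing=float(spacing),
        snapshots_per_row=snapshots_per_row,
        r_min=r_min,
        r_max=r_max,
        viewer=viewer,
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _offsets(spec: FlipbookSpec) -> list[tuple[float, float]]:
    per_row = spec.snapshots_per_row or len(spec.snapshot_paths)
    out = []
    for k in range(len(spec.snapshot_paths)):
        out.append(((k % per_row) * spec.spacing, -(k // per_row) * spec.spacing))
    return out


def _stop_pairs(spec: FlipbookSpec) -> list[tuple[float, str]]:
    values = [spec.vmin + f * (spec.vmax - spec.vmin) for f in STOP_FRACTIONS]
    return list(zip(values, palette_stops(spec.palette)))


def generate_chimerax_script(spec: FlipbookSpec, path: str | Path) -> Path:
    """Emit a deterministic ChimeraX command script (.cxc) for the flipbook.

    The script opens each snapshot, superposes models 2..n onto the first,
    offsets them along the layout, colors by the B-factor attribute with
    explicit palette stops over (vmin, vmax), maps B-factor linearly to
    worm radius in (r_min, r_max), and saves a transparent-background PNG.
    """
    n = len(spec.snapshot_paths)
    stops = ":".join(f"{_fmt(v)},{c}" for v, c in _stop_pairs(spec))
    lines = [
        f"# flipbook of {n} snapshots | kind={spec.kind} palette={spec.palette} "
        f"vmin={_fmt(spec.vmin)} vmax={_fmt(spec.vmax)}",
    ]
    for p in spec.snapshot_paths:
        lines.append(f"open {p}")
    if n > 1:
        lines.append(f"matchmaker #2-{n} to #1")
    for k, (dx, dy) in enumerate(_offsets(spec), start=1):
        if k == 1:
            continue  # first model anchors the layout
        lines.append(f"move x {_fmt(dx)} models #{k} coordinateSystem scene")
        if dy:
            lines.append(f"move y {_fmt(dy)} models #{k} coordinateSystem scene")
    lines += [
        f"color byattribute bfactor #1-{n} palette {stops}",
        "cartoon style protein modeHelix tube sides 20",
        "worm on",
        f"size byattribute bfactor worm {_fmt(spec.vmin)}:{_fmt(spec.r_min)} "
        f"{_fmt(spec.vmax)}:{_fmt(spec.r_max)} noValue {_fmt(spec.r_min)}",
        "view",
        "save flipbook.png transparentBackground true",
    ]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def generate_vmd_script(spec: FlipbookSpec, path: str | Path) -> Path:
    """Emit a deterministic VMD Tcl script for the flipbook.

    Snapshots load as separate molecules, each offset by a per-molecule
    transform (VMD has no per-model pivot points, so offsets are baked into
    the molecules' global matrices). Residue color follows the B-factor
    (beta) field through the same palette stops as the ChimeraX script, and
    tube radius is mapped linearly from (vmin, vmax) to (r_min, r_max).
    Convenience procs control spacing and simultaneous rotation.
    """
    n = len(spec.snapshot_paths)
    stop_list = " ".join("{%s %s}" % (_fmt(v), c) for v, c in _stop_pairs(spec))
    lines = [
        f"# flipbook of {n} snapshots | kind={spec.kind} palette={spec.palette} "
        f"vmin={_fmt(spec.vmin)} vmax={_fmt(spec.vmax)}",
        f"set flipbook_vmin {_fmt(spec.vmin)}",
        f"set flipbook_vmax {_fmt(spec.vmax)}",
        f"set flipbook_rmin {_fmt(spec.r_min)}",
        f"set flipbook_rmax {_fmt(spec.r_max)}",
        f"set flipbook_spacing {_fmt(spec.spacing)}",
        f"set flipbook_color_stops [list {stop_list}]",
        "# radius lookup: beta=vmin -> r_min, beta=vmax -> r_max (linear, clamped)",
        f"set flipbook_radius_map [list {{{_fmt(spec.vmin)} {_fmt(spec.r_min)}}} "
        f"{{{_fmt(spec.vmax)} {_fmt(spec.r_max)}}}]",
        "proc flipbook_radius {b} {",
        "    global flipbook_vmin flipbook_vmax flipbook_rmin flipbook_rmax",
        "    set f [expr {($b - $flipbook_vmin) / ($flipbook_vmax - $flipbook_vmin)}]",
        "    if {$f < 0} {set f 0}",
        "    if {$f > 1} {set f 1}",
        "    return [expr {$flipbook_rmin + $f * ($flipbook_rmax - $flipbook_rmin)}]",
        "}",
        "proc flipbook_offset {mol dx dy} {",
        "    set sel [atomselect $mol all]",
        "    $sel moveby [list $dx $dy 0]",
        "    $sel delete",
        "}",
        "proc flipbook_rotate_all {axis angle} {",
        "    foreach m [molinfo list] {",
        "        set sel [atomselect $m all]",
        "        $sel move [trans axis $axis $angle deg]",
        "        $sel delete",
        "    }",
        "}",
        "proc flipbook_respace {spacing} {",
        "    set k 0",
        "    foreach m [molinfo list] {",
        "        flipbook_offset $m [expr {$k * $spacing}] 0",
        "        incr k",
        "    }",
        "}",
    ]
    for (dx, dy), p in zip(_offsets(spec), spec.snapshot_paths):
        lines.append(f"mol new {{{p}}} type pdb waitfor all")
        lines.append(f"flipbook_offset top {_fmt(dx)} {_fmt(dy)}")
    lines += [
        "# per-residue tube radius and beta coloring with the shared palette",
        "foreach m [molinfo list] {",
        "    mol delrep 0 $m",
        "    set rid 0",
        "    set sel [atomselect $m all]",
        "    foreach resid [lsort -integer -unique [$sel get resid]] {",
        "        set rsel [atomselect $m \"resid $resid\"]",
        "        set beta [lindex [$rsel get beta] 0]",
        "        mol representation Tube [flipbook_radius $beta] 12",
        "        mol color Beta",
        "        mol selection \"resid $resid\"",
        "        mol addrep $m",
        "        incr rid",
        "        $rsel delete",
        "    }",
        "    $sel delete",
        "}",
        "color scale method BWR",
        "render snapshot flipbook_vmd.png",
    ]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
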
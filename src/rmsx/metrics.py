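"""Windowed per-residue fluctuation analysis and companion metrics.

The central quantity is the windowed RMSF matrix: the analyzed frame
range is cut into equal consecutive windows and, within each window, a
standard per-residue RMSF is computed about the within-window mean
position,

    RMSF_i = sqrt( (1/T) * sum_t || r_i(t) - <r_i> ||^2 ),

and the window-wise profiles are concatenated into a residues x windows
matrix. Shift maps (per-residue Euclidean displacement from a reference
frame) and per-residue lDDT time series are provided as complementary
residue-by-time matrices, together with Pearson benchmarking and a
window-size comparison heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, EmptySelectionError, RmsxError, SlicingError
from .slicing import SlicePlan, plan_slices, slice_time_axis
from .structure_io import AtomSelection, TrajectorySystem
from .superposition import _batched_fit, align_trajectory, rmsd_series

__all__ = [
    "MetricMatrix",
    "WindowCheckEntry",
    "WindowCheckReport",
    "DEFAULT_LDDT_R0",
    "DEFAULT_LDDT_THRESHOLDS",
    "DEFAULT_WINDOW_CANDIDATES",
    "window_rmsf",
    "compute_rmsx",
    "classic_rmsf",
    "mean_rmsx_per_residue",
    "mean_rmsx_per_slice",
    "shift_map",
    "lddt_series",
    "average_per_slice",
    "pearson",
    "window_check",
]

# Standard published defaults for the local distance difference test:
# CA atoms, 15 Å inclusion radius, thresholds 0.5/1/2/4 Å.
DEFAULT_LDDT_R0 = 15.0
DEFAULT_LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)

DEFAULT_WINDOW_CANDIDATES = (4, 8, 16, 32, 64, 128)


@dataclass
class MetricMatrix:
    """Residues x time-bins scalar matrix with axis labels.

    ``kind`` is one of ``rmsx``/``shift`` (Å, >= 0) or ``lddt`` (unitless
    in [0, 1], NaN where a residue has no reference contacts). For
    window-based matrices ``plan`` carries the partition; for per-frame
    matrices ``frame_indices`` maps columns to trajectory frames.
    ``time_edges_ns`` has ``n_bins + 1`` entries.
    """

    kind: str
    values: np.ndarray
    residue_labels: list[tuple[str, int, str]]
    time_edges_ns: np.ndarray
    plan: SlicePlan | None = None
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("rmsx", "shift", "lddt"):
            raise RmsxError(f"unknown metric kind {self.kind!r}")
        if self.values.ndim != 2:
            raise RmsxError("metric values must be a 2-D residues x bins array")
        if self.values.shape[0] != len(self.residue_labels):
            raise RmsxError(
                f"{len(self.residue_labels)} residue labels for "
                f"{self.values.shape[0]} rows"
            )
        if len(self.time_edges_ns) != self.values.shape[1] + 1:
            raise RmsxError("time_edges_ns must have n_bins + 1 entries")
        finite = self.values[np.isfinite(self.values)]
        if self.kind in ("rmsx", "shift") and np.any(finite < -1e-12):
            raise RmsxError(f"{self.kind} values must be non-negative")
        if self.kind == "lddt" and (np.any(finite < -1e-12) or np.any(finite > 1 + 1e-12)):
            raise RmsxError("lddt values must lie in [0, 1]")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def _group_positions(coords: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-residue representative positions: (T, n_residues, 3).

    Single-atom groups use the atom directly; multi-atom groups their
    centroid."""
    if all(g.size == 1 for g in groups):
        idx = np.concatenate(groups)
        return coords[:, idx, :]
    return np.stack([coords[:, g, :].mean(axis=1) for g in groups], axis=1)


def window_rmsf(
    coords_window: np.ndarray,
    selection: AtomSelection,
    per_atom_mean: bool = True,
) -> np.ndarray:
    """Per-residue RMSF (Å) of one window of frames.

    ``coords_window`` has shape ``(T, n_atoms_total, 3)`` with ``T >= 2``.
    With ``per_atom_mean`` (default) the RMSF is computed per selected atom
    and averaged within each residue; single-atom residues (the default CA
    selection) are unaffected by the choice.
    """
    coords = np.asarray(coords_window, dtype=float)
    if coords.ndim != 3:
        raise RmsxError("coords_window must have shape (T, n_atoms, 3)")
    if coords.shape[0] < 2:
        raise SlicingError(
            f"window too short for fluctuation: {coords.shape[0]} frame(s)"
        )
    if selection.n_atoms == 0:
        raise EmptySelectionError("window_rmsf requires a non-empty selection")

    sel = coords[:, selection.indices, :]
    mean = sel.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((sel - mean) ** 2, axis=2), axis=0))
    pos_of = {int(a): i for i, a in enumerate(selection.indices)}
    out = np.empty(selection.n_residues)
    if per_atom_mean:
        for r, group in enumerate(selection.residue_groups):
            out[r] = per_atom[[pos_of[int(a)] for a in group]].mean()
    else:
        centroids = _group_positions(coords, selection.residue_groups)
        mean_c = centroids.mean(axis=0)
        out = np.sqrt(np.mean(np.sum((centroids - mean_c) ** 2, axis=2), axis=0))
    return out


def _aligned_range(
    system: TrajectorySystem,
    plan: SlicePlan,
    selection: AtomSelection,
    align_mode: str,
) -> np.ndarray:
    """Coordinates of the analyzed range after the requested pre-alignment."""
    coords = system.coords[plan.start_frame : plan.start_frame + plan.analyzed_frames]
    if align_mode == "none":
        return coords
    if align_mode == "global":
        sub = TrajectorySystem(
            names=system.names,
            resids=system.resids,
            resnames=system.resnames,
            chain_ids=system.chain_ids,
            elements=system.elements,
            coords=coords,
            dt_ps=system.dt_ps,
            source_paths=system.source_paths,
        )
        return align_trajectory(sub, selection, reference_frame=0).coords
    if align_mode == "window":
        idx = selection.indices
        out = np.empty_like(coords)
        for k in range(plan.n_slices):
            lo = k * plan.frames_per_slice
            hi = lo + plan.frames_per_slice
            block = coords[lo:hi]
            # one pass: fit to the first frame, then refit to the mean
            rot, trans, _ = _batched_fit(block[:, idx, :], block[0, idx])
            pre = np.einsum("fij,fnj->fni", rot, block) + trans[:, None, :]
            mean = pre[:, idx, :].mean(axis=0)
            rot, trans, _ = _batched_fit(block[:, idx, :], mean)
            out[lo:hi] = np.einsum("fij,fnj->fni", rot, block) + trans[:, None, :]
        return out
    raise RmsxError(f"unknown align_mode {align_mode!r}; use global/window/none")


def compute_rmsx(
    system: TrajectorySystem,
    plan: SlicePlan,
    selection: AtomSelection,
    align_mode: str = "global",
) -> MetricMatrix:
    """Windowed per-residue RMSF matrix (residues x n_slices).

    Column *k* is the per-residue RMSF over the frames of window *k*. By
    default the whole analyzed range is first superposed onto its first
    frame on the selection (``align_mode="global"``); ``"window"`` refits
    each window to its own mean structure, ``"none"`` skips alignment.
    """
    if selection.n_residues == 0:
        raise EmptySelectionError("compute_rmsx requires a non-empty selection")
    coords = _aligned_range(system, plan, selection, align_mode)
    values = np.empty((selection.n_residues, plan.n_slices))
    for k in range(plan.n_slices):
        lo = k * plan.frames_per_slice
        values[:, k] = window_rmsf(coords[lo : lo + plan.frames_per_slice], selection)
    return MetricMatrix(
        kind="rmsx",
        values=values,
        residue_labels=list(selection.residue_keys),
        time_edges_ns=slice_time_axis(plan),
        plan=plan,
    )


def classic_rmsf(
    system: TrajectorySystem,
    selection: AtomSelection,
    start_frame: int = 0,
    end_frame: int | None = None,
    align_mode: str = "global",
) -> np.ndarray:
    """Standard per-residue RMSF over the full analyzed range."""
    plan = plan_slices(
        system.n_frames,
        start_frame=start_frame,
        end_frame=end_frame,
        n_slices=1,
        dt_ps=system.dt_ps,
    )
    return compute_rmsx(system, plan, selection, align_mode=align_mode).values[:, 0]


def mean_rmsx_per_residue(matrix: MetricMatrix) -> np.ndarray:
    """Time-averaged value per residue: mean across all slices of the matrix."""
    if matrix.kind != "rmsx":
        raise RmsxError(f"expected an rmsx matrix, got kind {matrix.kind!r}")
    return matrix.values.mean(axis=1)


def mean_rmsx_per_slice(matrix: MetricMatrix) -> np.ndarray:
    """Per-slice value averaged over residues."""
    if matrix.kind != "rmsx":
        raise RmsxError(f"expected an rmsx matrix, got kind {matrix.kind!r}")
    return matrix.values.mean(axis=0)


def shift_map(
    system: TrajectorySystem,
    selection: AtomSelection,
    reference_frame: int = 0,
    align: bool = True,
) -> MetricMatrix:
    """Per-residue Euclidean displacement from a reference frame, per frame.

    Entry ``(i, t)`` is ``||r_i(t) - r_i(reference)||`` in Å. With
    ``align`` (default) each frame is first rigidly superposed onto the
    reference on the fit selection, so the map reports internal
    rearrangement; disable it for pulling simulations where lab-frame
    drift is the signal.
    """
    if selection.n_residues == 0:
        raise EmptySelectionError("shift_map requires a non-empty selection")
    if not 0 <= reference_frame < system.n_frames:
        raise DegenerateInputError(
            f"reference_frame {reference_frame} out of range [0, {system.n_frames})"
        )
    work = (
        align_trajectory(system, selection, reference_frame) if align else system
    )
    pos = _group_positions(work.coords, selection.residue_groups)
    disp = np.linalg.norm(pos - pos[reference_frame], axis=2)  # (T, R)
    times = np.arange(system.n_frames + 1) * system.dt_ps / 1000.0
    return MetricMatrix(
        kind="shift",
        values=disp.T,
        residue_labels=list(selection.residue_keys),
        time_edges_ns=times,
        frame_indices=np.arange(system.n_frames),
    )


def lddt_series(
    system: TrajectorySystem,
    selection: AtomSelection,
    reference_frame: int = 0,
    r0: float = DEFAULT_LDDT_R0,
    thresholds: tuple[float, ...] = DEFAULT_LDDT_THRESHOLDS,
) -> MetricMatrix:
    """Per-residue local-distance-difference scores versus a reference frame.

    The distance set is fixed by the reference: all selection-atom pairs in
    different residues with reference distance < ``r0``. The score of
    residue *i* at frame *t* is the mean over thresholds of the fraction of
    *i*'s reference distances preserved within the threshold. Residues with
    no reference contacts are NaN (undefined), never 0.
    """
    if selection.n_atoms == 0:
        raise EmptySelectionError("lddt_series requires a non-empty selection")
    if not thresholds or list(thresholds) != sorted(thresholds):
        raise RmsxError("thresholds must be non-empty and ascending")
    if not r0 > 0:
        raise RmsxError(f"inclusion radius must be > 0, got {r0}")
    if not 0 <= reference_frame < system.n_frames:
        raise DegenerateInputError(
            f"reference_frame {reference_frame} out of range [0, {system.n_frames})"
        )

    idx = selection.indices
    n_sel = idx.size
    res_of = np.empty(n_sel, dtype=int)
    for r, group in enumerate(selection.residue_groups):
        for a in group:
            res_of[np.searchsorted(idx, a)] = r

    ref = system.coords[reference_frame, idx]
    ii, jj = np.triu_indices(n_sel, k=1)
    keep = res_of[ii] != res_of[jj]
    ii, jj = ii[keep], jj[keep]
    d_ref = np.linalg.norm(ref[ii] - ref[jj], axis=1)
    keep = d_ref < r0
    ii, jj, d_ref = ii[keep], jj[keep], d_ref[keep]

    n_res = selection.n_residues
    counts = np.zeros(n_res)
    np.add.at(counts, res_of[ii], 1)
    np.add.at(counts, res_of[jj], 1)

    thr = np.asarray(thresholds, dtype=float)
    n_frames = system.n_frames
    scores = np.full((n_res, n_frames), np.nan)
    defined = counts > 0
    sel_coords = system.coords[:, idx, :]
    for t in range(n_frames):
        d_t = np.linalg.norm(sel_coords[t, ii] - sel_coords[t, jj], axis=1)
        # preserved fraction averaged over thresholds, per pair
        pair_score = (np.abs(d_ref - d_t)[:, None] < thr[None, :]).mean(axis=1)
        acc = np.zeros(n_res)
        np.add.at(acc, res_of[ii], pair_score)
        np.add.at(acc, res_of[jj], pair_score)
        scores[defined, t] = acc[defined] / counts[defined]

    times = np.arange(n_frames + 1) * system.dt_ps / 1000.0
    return MetricMatrix(
        kind="lddt",
        values=scores,
        residue_labels=list(selection.residue_keys),
        time_edges_ns=times,
        frame_indices=np.arange(n_frames),
    )


def average_per_slice(matrix: MetricMatrix, plan: SlicePlan) -> MetricMatrix:
    """Average a per-frame matrix (shift/lddt) into the windows of a plan.

    NaN cells are ignored within each window (a residue undefined at every
    frame of a window stays NaN).
    """
    if matrix.frame_indices is None:
        raise RmsxError("matrix is already window-based")
    values = np.empty((matrix.n_residues, plan.n_slices))
    for k, (lo, hi) in enumerate(plan.slice_bounds):
        cols = (matrix.frame_indices >= lo) & (matrix.frame_indices < hi)
        if not cols.any():
            raise SlicingError(f"window [{lo}, {hi}) covers no matrix columns")
        with np.errstate(invalid="ignore"):
            values[:, k] = np.nanmean(matrix.values[:, cols], axis=1)
    return MetricMatrix(
        kind=matrix.kind,
        values=values,
        residue_labels=list(matrix.residue_labels),
        time_edges_ns=slice_time_axis(plan),
        plan=plan,
    )


def pearson(x_series, y_series) -> tuple[float, float]:
    """Product-moment correlation ``(r, r_squared)`` of two equal-length series."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError(
            f"series must be 1-D with equal lengths, got {x.shape} vs {y.shape}"
        )
    if x.size < 3:
        raise DegenerateInputError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate series: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, r * r


@dataclass(frozen=True)
class WindowCheckEntry:
    n_slices: int
    frames_per_slice: int
    pearson_r: float | None
    r_squared: float | None
    skipped: bool = False
    reason: str = ""


@dataclass(frozen=True)
class WindowCheckReport:
    """Correlation of mean windowed RMSF with mean RMSD per window, across
    candidate window counts."""

    entries: tuple[WindowCheckEntry, ...]

    def best(self) -> WindowCheckEntry:
        live = [e for e in self.entries if not e.skipped]
        if not live:
            raise RmsxError("all window candidates were skipped")
        return max(live, key=lambda e: e.pearson_r)


def window_check(
    system: TrajectorySystem,
    selection: AtomSelection,
    candidate_slice_counts=DEFAULT_WINDOW_CANDIDATES,
    start_frame: int = 0,
    end_frame: int | None = None,
    align_mode: str = "global",
) -> WindowCheckReport:
    """Compare window sizes by correlating mean windowed RMSF against RMSD.

    For each candidate slice count a plan is built over the analyzed range;
    the per-slice mean of the windowed RMSF matrix is correlated (Pearson)
    with the per-slice mean of the per-frame RMSD versus the first analyzed
    frame. Candidates that do not fit the range are marked skipped.
    """
    if end_frame is None:
        end_frame = system.n_frames
    span = end_frame - start_frame
    rmsd = rmsd_series(system, selection, reference_frame=start_frame).values
    entries: list[WindowCheckEntry] = []
    for cand in candidate_slice_counts:
        if cand < 2:
            entries.append(
                WindowCheckEntry(cand, 0, None, None, True, "need >= 2 slices")
            )
            continue
        if cand > span or span // cand < 2:
            entries.append(
                WindowCheckEntry(
                    cand, 0, None, None, True,
                    f"{cand} slices do not fit {span} frames (need >= 2 frames per slice)",
                )
            )
            continue
        plan = plan_slices(
            system.n_frames,
            start_frame=start_frame,
            end_frame=end_frame,
            n_slices=cand,
            dt_ps=system.dt_ps,
        )
        matrix = compute_rmsx(system, plan, selection, align_mode=align_mode)
        mean_x = mean_rmsx_per_slice(matrix)
        mean_d = np.array(
            [rmsd[lo - start_frame : hi - start_frame].mean() for lo, hi in plan.slice_bounds]
        )
        try:
            r, r2 = pearson(mean_x, mean_d)
        except DegenerateInputError as exc:
            entries.append(
                WindowCheckEntry(cand, plan.frames_per_slice, None, None, True, str(exc))
            )
            continue
        entries.append(WindowCheckEntry(cand, plan.frames_per_slice, r, r2))
    return WindowCheckReport(entries=tuple(entries))
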
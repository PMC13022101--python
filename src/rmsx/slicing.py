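"""Partition a frame range into equal consecutive windows.

A trajectory range is divided into either a user-specified number of
slices or a fixed number of frames per slice; when the range is not
evenly divisible the excess frames at the end are dropped. The plan also
reports total analyzed frames and the equivalent simulation time in ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SlicingError

__all__ = ["SlicePlan", "plan_slices", "slice_time_axis"]


@dataclass(frozen=True)
class SlicePlan:
    """Partition of ``[start_frame, end_frame)`` into equal windows.

    ``slice_bounds[k]`` is the half-open frame interval of window *k*;
    windows are consecutive, non-overlapping and ordered, and
    ``n_slices * frames_per_slice + dropped_frames == end_frame - start_frame``.
    """

    start_frame: int
    end_frame: int
    n_slices: int
    frames_per_slice: int
    dropped_frames: int
    slice_bounds: tuple[tuple[int, int], ...]
    dt_ps: float

    @property
    def analyzed_frames(self) -> int:
        return self.n_slices * self.frames_per_slice

    @property
    def analyzed_time_ns(self) -> float:
        return self.analyzed_frames * self.dt_ps / 1000.0

    @property
    def range_frames(self) -> int:
        return self.end_frame - self.start_frame

    def describe(self) -> str:
        return (
            f"{self.n_slices} slices x {self.frames_per_slice} frames "
            f"({self.dropped_frames} dropped); {self.analyzed_frames} frames "
            f"analyzed = {self.analyzed_time_ns:g} ns at dt {self.dt_ps:g} ps"
        )


def plan_slices(
    n_frames_available: int,
    start_frame: int = 0,
    end_frame: int | None = None,
    n_slices: int | None = None,
    frames_per_slice: int | None = None,
    dt_ps: float = 1.0,
) -> SlicePlan:
    """Plan equal consecutive windows over ``[start_frame, end_frame)``.

    Exactly one of ``n_slices`` / ``frames_per_slice`` must be given. With
    ``n_slices``, the window length is ``floor(range / n_slices)``; with
    ``frames_per_slice``, the count is ``floor(range / frames_per_slice)``.
    The remainder is dropped from the end in both cases.
    """
    if end_frame is None:
        end_frame = n_frames_available
    if not dt_ps > 0:
        raise SlicingError(f"dt_ps must be > 0, got {dt_ps}")
    if not (0 <= start_frame < end_frame <= n_frames_available):
        raise SlicingError(
            f"invalid frame range [{start_frame}, {end_frame}) for "
            f"{n_frames_available} available frames"
        )
    if (n_slices is None) == (frames_per_slice is None):
        raise SlicingError("give exactly one of n_slices / frames_per_slice")

    span = end_frame - start_frame
    if n_slices is not None:
        if n_slices < 1:
            raise SlicingError(f"n_slices must be >= 1, got {n_slices}")
        if n_slices > span:
            raise SlicingError(
                f"cannot cut {span} frames into {n_slices} slices"
            )
        frames_per_slice = span // n_slices
    else:
        assert frames_per_slice is not None
        if frames_per_slice < 1:
            raise SlicingError(
                f"frames_per_slice must be >= 1, got {frames_per_slice}"
            )
        if frames_per_slice > span:
            raise SlicingError(
                f"window longer than trajectory: {frames_per_slice} frames "
                f"requested but the range holds only {span}"
            )
        n_slices = span // frames_per_slice

    dropped = span - n_slices * frames_per_slice
    bounds = tuple(
        (
            start_frame + k * frames_per_slice,
            start_frame + (k + 1) * frames_per_slice,
        )
        for k in range(n_slices)
    )
    return SlicePlan(
        start_frame=start_frame,
        end_frame=end_frame,
        n_slices=n_slices,
        frames_per_slice=frames_per_slice,
        dropped_frames=dropped,
        slice_bounds=bounds,
        dt_ps=float(dt_ps),
    )


def slice_time_axis(plan: SlicePlan, kind: str = "edges") -> np.ndarray:
    """Window edge (or midpoint) times in ns.

    Edge *k* sits at ``(start_frame + k * frames_per_slice) * dt_ps / 1000``;
    with ``kind="edges"`` the array has ``n_slices + 1`` entries, with
    ``kind="mid"`` it has ``n_slices``.
    """
    edges = (
        plan.start_frame
        + np.arange(plan.n_slices + 1) * plan.frames_per_slice
    ) * plan.dt_ps / 1000.0
    if kind == "edges":
        return edges
    if kind == "mid":
        return 0.5 * (edges[:-1] + edges[1:])
    raise SlicingError(f"unknown time-axis kind {kind!r}; use 'edges' or 'mid'")
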
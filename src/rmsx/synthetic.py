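"""Synthetic structure+trajectory generator with known fluctuation statistics.

Every metric in the package is testable offline against trajectories whose
fluctuation statistics have closed forms: isotropic Gaussian jitter of
per-coordinate width sigma contributes sigma * sqrt(3) to the per-residue
RMSF, a sinusoid of amplitude A over whole periods contributes A / sqrt(2)
on its axis, and the two combine in quadrature. Optional events (locally
scaled noise in a frame window), linear drift, and rigid tumbling exercise
the windowed-fluctuation, shift-map, and alignment code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import RmsxError
from .structure_io import TrajectorySystem, write_multimodel_pdb, write_pdb_frame

__all__ = ["Event", "SyntheticSpec", "build_system", "generate", "expected_rmsf"]

CA_SPACING = 3.8  # Å between consecutive alpha carbons on the line geometry

AMINO3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


@dataclass(frozen=True)
class Event:
    """Noise-amplitude event: residues [res_start, res_stop) get their sigma
    multiplied during frames [frame_start, frame_stop)."""

    res_start: int
    res_stop: int
    frame_start: int
    frame_stop: int
    multiplier: float


@dataclass
class SyntheticSpec:
    """Generative parameters with analytic expectations.

    ``sigma`` and ``sinusoid_amplitude`` may be scalars or per-residue
    arrays (Å). The sinusoid acts on the y-axis; drift is a constant
    Å/frame vector; ``tumble`` applies a random rigid transform per frame.
    """

    n_residues: int = 20
    n_frames: int = 100
    dt_ps: float = 10.0
    geometry: str = "line"  # or "helix"
    sigma: float | np.ndarray = 0.3
    sinusoid_amplitude: float | np.ndarray = 0.0
    sinusoid_period: int = 20
    events: tuple[Event, ...] = ()
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tumble: bool = False
    n_chains: int = 1
    backbone: str = "ca"  # or "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_frames < 1:
            raise RmsxError("need at least one residue and one frame")
        if self.geometry not in ("line", "helix"):
            raise RmsxError(f"unknown geometry {self.geometry!r}")
        if self.backbone not in ("ca", "full"):
            raise RmsxError(f"unknown backbone mode {self.backbone!r}")
        if self.n_chains not in (1, 2):
            raise RmsxError("n_chains must be 1 or 2")
        if np.any(np.asarray(self.sigma) < 0):
            raise RmsxError("sigma must be >= 0")
        for ev in self.events:
            if not (0 <= ev.frame_start < ev.frame_stop <= self.n_frames):
                raise RmsxError(
                    f"event frames [{ev.frame_start}, {ev.frame_stop}) outside "
                    f"[0, {self.n_frames})"
                )

    def sigma_per_residue(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.sigma, dtype=float), (self.n_residues,)
        ).copy()

    def amplitude_per_residue(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.sinusoid_amplitude, dtype=float), (self.n_residues,)
        ).copy()

    def to_json(self) -> str:
        payload = asdict(self)
        payload["sigma"] = np.asarray(self.sigma).tolist()
        payload["sinusoid_amplitude"] = np.asarray(self.sinusoid_amplitude).tolist()
        payload["events"] = [asdict(e) for e in self.events]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        payload = json.loads(text)
        payload["events"] = tuple(Event(**e) for e in payload.get("events", []))
        payload["drift"] = tuple(payload.get("drift", (0.0, 0.0, 0.0)))
        for key in ("sigma", "sinusoid_amplitude"):
            if isinstance(payload.get(key), list):
                payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def _base_geometry(spec: SyntheticSpec) -> np.ndarray:
    i = np.arange(spec.n_residues, dtype=float)
    if spec.geometry == "line":
        # zig-zag rather than a perfect line so rigid-body fits are well-posed
        return np.stack(
            [i * CA_SPACING, 1.0 * (-1.0) ** i, np.zeros_like(i)], axis=1
        )
    # ideal alpha-helix CA trace: 2.3 Å radius, 100 deg turn, 1.5 Å rise
    theta = np.deg2rad(100.0) * i
    return np.stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _residue_trajectories(spec: SyntheticSpec) -> np.ndarray:
    """CA positions per frame for one chain: (n_frames, n_residues, 3)."""
    rng = np.random.default_rng(spec.seed)
    base = _base_geometry(spec)
    sigma = spec.sigma_per_residue()
    amp = spec.amplitude_per_residue()
    frames = np.arange(spec.n_frames, dtype=float)

    sigma_ft = np.broadcast_to(sigma, (spec.n_frames, spec.n_residues)).copy()
    for ev in spec.events:
        sigma_ft[ev.frame_start : ev.frame_stop, ev.res_start : ev.res_stop] *= (
            ev.multiplier
        )

    noise = rng.normal(size=(spec.n_frames, spec.n_residues, 3))
    noise *= sigma_ft[:, :, None]
    coords = base[None, :, :] + noise
    if np.any(amp > 0):
        phase = np.sin(2 * np.pi * frames / spec.sinusoid_period)
        coords[:, :, 1] += phase[:, None] * amp[None, :]
    drift = np.asarray(spec.drift, dtype=float)
    if np.any(drift != 0):
        coords += frames[:, None, None] * drift[None, None, :]
    if spec.tumble:
        for t in range(spec.n_frames):
            rot = _random_rotation(rng)
            shift = rng.normal(scale=5.0, size=3)
            coords[t] = coords[t] @ rot.T + shift
    return coords


# ideal peptide-plane offsets relative to the CA, used by backbone="full"
_BACKBONE_OFFSETS = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "C": np.array([1.52, 0.3, 0.0]),
    "O": np.array([2.15, 1.35, 0.0]),
}


def build_system(spec: SyntheticSpec) -> TrajectorySystem:
    """Materialize the spec as an in-memory TrajectorySystem."""
    chain_blocks = []
    for c in range(spec.n_chains):
        chain_spec = spec if c == 0 else SyntheticSpec(
            **{**_spec_dict(spec), "seed": spec.seed + 104729 * c}
        )
        coords = _residue_trajectories(chain_spec)
        if c == 1:
            coords = coords + np.array([0.0, 0.0, 20.0])  # stack second chain in z
        chain_blocks.append(coords)

    names, resids, resnames, chains, elements = [], [], [], [], []
    atom_coords = []
    for c, block in enumerate(chain_blocks):
        chain_id = "AB"[c]
        for i in range(spec.n_residues):
            resname = AMINO3[i % len(AMINO3)]
            atom_names = ["CA"] if spec.backbone == "ca" else ["N", "CA", "C", "O"]
            for atom in atom_names:
                names.append(atom)
                resids.append(i + 1)
                resnames.append(resname)
                chains.append(chain_id)
                elements.append(atom[0])
                if atom == "CA":
                    atom_coords.append(block[:, i, :])
                else:
                    atom_coords.append(block[:, i, :] + _BACKBONE_OFFSETS[atom])
    coords = np.stack(atom_coords, axis=1)
    return TrajectorySystem(
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=coords,
        dt_ps=spec.dt_ps,
        source_paths=(f"synthetic(seed={spec.seed})",),
    )


def _spec_dict(spec: SyntheticSpec) -> dict:
    return {
        "n_residues": spec.n_residues,
        "n_frames": spec.n_frames,
        "dt_ps": spec.dt_ps,
        "geometry": spec.geometry,
        "sigma": spec.sigma,
        "sinusoid_amplitude": spec.sinusoid_amplitude,
        "sinusoid_period": spec.sinusoid_period,
        "events": spec.events,
        "drift": spec.drift,
        "tumble": spec.tumble,
        "n_chains": 1,
        "backbone": spec.backbone,
        "seed": spec.seed,
    }


def generate(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write structure PDB + trajectory (multi-model PDB and DCD) files.

    Output is deterministic for a fixed seed. Returns a mapping with keys
    ``structure``, ``trajectory_pdb``, ``trajectory_dcd``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    system = build_system(spec)

    structure = out_dir / "structure.pdb"
    write_pdb_frame(system, 0, None, structure)
    trajectory_pdb = out_dir / "trajectory.pdb"
    write_multimodel_pdb(system, trajectory_pdb)

    trajectory_dcd = out_dir / "trajectory.dcd"
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(structure), str(trajectory_pdb))
        with mda.Writer(str(trajectory_dcd), n_atoms=system.n_atoms) as writer:
            for _ in universe.trajectory:
                writer.write(universe.atoms)

    (out_dir / "spec.json").write_text(spec.to_json() + "\n")
    return {
        "structure": structure,
        "trajectory_pdb": trajectory_pdb,
        "trajectory_dcd": trajectory_dcd,
    }


def expected_rmsf(
    spec: SyntheticSpec, window: tuple[int, int] | None = None
) -> np.ndarray:
    """Analytic per-residue RMSF expectation for a frame window.

    Gaussian jitter contributes ``sigma * sqrt(3)``; a sinusoid of amplitude
    A over whole periods contributes ``A / sqrt(2)``; the terms combine in
    quadrature. The window must not intersect drift, tumbling, or partial
    event overlap, and must span whole sinusoid periods when A > 0.
    """
    if window is None:
        window = (0, spec.n_frames)
    lo, hi = window
    if not (0 <= lo < hi <= spec.n_frames):
        raise RmsxError(f"window [{lo}, {hi}) outside [0, {spec.n_frames})")
    if spec.tumble:
        raise RmsxError("no closed-form RMSF with rigid tumbling; align first")
    if np.any(np.asarray(spec.drift) != 0):
        raise RmsxError("no closed-form RMSF with drift; use a drift-free spec")

    sigma = spec.sigma_per_residue()
    amp = spec.amplitude_per_residue()
    if np.any(amp > 0) and (hi - lo) % spec.sinusoid_period != 0:
        raise RmsxError(
            f"window of {hi - lo} frames is not a whole number of sinusoid "
            f"periods ({spec.sinusoid_period})"
        )

    mult = np.ones(spec.n_residues)
    for ev in spec.events:
        inside = ev.frame_start <= lo and hi <= ev.frame_stop
        outside = ev.frame_stop <= lo or hi <= ev.frame_start
        if inside:
            mult[ev.res_start : ev.res_stop] *= ev.multiplier
        elif not outside:
            raise RmsxError(
                "window partially overlaps an event; no closed-form RMSF"
            )
    sigma_eff = sigma * mult
    return np.sqrt(3.0 * sigma_eff**2 + 0.5 * amp**2)
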
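"""Structure and trajectory I/O.

Reads a structure file (PDB) together with a trajectory (multi-model PDB,
DCD, XTC or TRR) into an in-memory :class:`TrajectorySystem`, splits
multi-chain systems, resolves atom selections, and writes fixed-column
PDB frames with metric values in the B-factor field.

Parsing of the on-disk formats is delegated to MDAnalysis; the in-memory
model is plain NumPy so downstream metric code never touches a Universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AtomCountMismatchError,
    EmptySelectionError,
    FormatError,
    RmsxError,
)

__all__ = [
    "TrajectorySystem",
    "AtomSelection",
    "load_system",
    "split_chains",
    "select_atoms",
    "write_pdb_frame",
]

TRAJECTORY_FORMATS = (".pdb", ".dcd", ".xtc", ".trr")

# B-factor column is %6.2f: representable range after clamping.
BFACTOR_MIN = 0.0
BFACTOR_MAX = 999.99


@dataclass
class TrajectorySystem:
    """Topology plus ordered coordinate frames.

    Attributes
    ----------
    names, resids, resnames, chain_ids, elements
        Per-atom topology arrays, all of length ``n_atoms``. ``resids``
        carry the author residue numbering from the input file.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å, temporally ordered.
    dt_ps
        Time between stored frames in picoseconds (> 0).
    source_paths
        Provenance strings (structure path, trajectory path).
    """

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    dt_ps: float
    source_paths: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise RmsxError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.names):
            raise RmsxError(
                f"coordinate frames carry {self.coords.shape[1]} atoms but the "
                f"topology has {len(self.names)}"
            )
        if not self.dt_ps > 0:
            raise RmsxError(f"dt_ps must be > 0, got {self.dt_ps}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique ``(chain_id, residue_id, residue_name)`` triples."""
        keys: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for chain, resid, resname in zip(self.chain_ids, self.resids, self.resnames):
            ident = (str(chain), int(resid))
            if ident not in seen:
                seen.add(ident)
                keys.append((str(chain), int(resid), str(resname)))
        return keys

    def subset(self, atom_indices: np.ndarray) -> "TrajectorySystem":
        """New system restricted to the given (ascending) atom indices."""
        idx = np.asarray(atom_indices, dtype=int)
        return TrajectorySystem(
            names=self.names[idx],
            resids=self.resids[idx],
            resnames=self.resnames[idx],
            chain_ids=self.chain_ids[idx],
            elements=self.elements[idx],
            coords=self.coords[:, idx, :],
            dt_ps=self.dt_ps,
            source_paths=self.source_paths,
        )


@dataclass
class AtomSelection:
    """A resolved atom selection: the predicate plus ascending atom indices.

    ``residue_keys[i]`` labels residue *i* and ``residue_groups[i]`` holds
    the selected atom indices belonging to it, so metrics can aggregate
    per residue without re-deriving the grouping.
    """

    indices: np.ndarray
    residue_keys: list[tuple[str, int, str]]
    residue_groups: list[np.ndarray]
    predicate: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size:
            if not np.all(np.diff(self.indices) > 0):
                raise RmsxError("selection indices must be unique and ascending")

    @property
    def n_atoms(self) -> int:
        return int(self.indices.size)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)


def _derive_elements(names: Sequence[str]) -> np.ndarray:
    out = []
    for name in names:
        stripped = str(name).strip()
        alpha = "".join(c for c in stripped if c.isalpha())
        out.append((alpha[:1] or "X").upper())
    return np.array(out, dtype=object)


def _trajectory_atom_count(path: Path) -> int | None:
    """Atom count from a trajectory file header, best effort."""
    import MDAnalysis as mda

    try:
        reader_cls = mda.coordinates.core.get_reader_for(str(path))
        reader = reader_cls(str(path))
        n = int(reader.n_atoms)
        reader.close()
        return n
    except Exception:
        return None


def load_system(
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    dt_ps: float | None = None,
    selection: str | None = None,
) -> TrajectorySystem:
    """Load a structure (+ optional trajectory) into a TrajectorySystem.

    Parameters
    ----------
    structure_path
        PDB structure file defining the topology.
    trajectory_path
        Trajectory file (multi-model PDB, DCD, XTC, TRR). When omitted the
        structure's own models provide the frames.
    dt_ps
        Time between stored frames in ps. Overrides any value found in the
        trajectory metadata; required when the file carries none.
    selection
        Optional MDAnalysis selection string applied at load time; pass
        ``"protein"`` to strip waters/ions for analysis.
    """
    import MDAnalysis as mda

    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FormatError(f"structure file not found: {structure_path}")
    if trajectory_path is not None:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise FormatError(f"trajectory file not found: {trajectory_path}")
        if trajectory_path.suffix.lower() not in TRAJECTORY_FORMATS:
            raise FormatError(
                f"unreadable trajectory format for {trajectory_path}: expected one of "
                + ", ".join(TRAJECTORY_FORMATS)
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(str(structure_path))
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise FormatError(
                f"could not read structure {structure_path} as PDB: {exc}"
            ) from exc
        n_structure = len(universe.atoms)
        if trajectory_path is not None:
            n_traj = _trajectory_atom_count(trajectory_path)
            if n_traj is not None and n_traj != n_structure:
                raise AtomCountMismatchError(
                    f"atom count mismatch: structure {structure_path} has "
                    f"{n_structure} atoms but trajectory {trajectory_path} has {n_traj}"
                )
            try:
                universe.load_new(str(trajectory_path))
            except Exception as exc:  # noqa: BLE001
                raise FormatError(
                    f"could not read trajectory {trajectory_path} "
                    f"(expected {', '.join(TRAJECTORY_FORMATS)}): {exc}"
                ) from exc

        icodes = getattr(universe.atoms, "icodes", None)
        if icodes is not None and any(str(c).strip() for c in icodes):
            raise RmsxError(
                "insertion codes are not supported; renumber residues first"
            )

        atoms = universe.atoms
        if selection:
            atoms = universe.select_atoms(selection)
            if len(atoms) == 0:
                raise EmptySelectionError(
                    f"selection {selection!r} matches no atoms in {structure_path}"
                )

        names = np.array([str(n) for n in atoms.names], dtype=object)
        resids = np.array([int(r) for r in atoms.resids], dtype=int)
        resnames = np.array([str(r) for r in atoms.resnames], dtype=object)
        try:
            chain_ids = np.array(
                [str(c).strip() or "A" for c in atoms.chainIDs], dtype=object
            )
        except (mda.exceptions.NoDataError, AttributeError):
            chain_ids = np.array(
                [str(s).strip() or "A" for s in atoms.segids], dtype=object
            )
        try:
            elements = np.array([str(e) for e in atoms.elements], dtype=object)
        except (mda.exceptions.NoDataError, AttributeError):
            elements = _derive_elements(names)

        frames = np.empty((len(universe.trajectory), len(atoms), 3), dtype=np.float64)
        for i, _ in enumerate(universe.trajectory):
            frames[i] = atoms.positions

        if dt_ps is None:
            dt_meta = getattr(universe.trajectory, "dt", None)
            if dt_meta is None or not dt_meta > 0:
                raise RmsxError(
                    "no time step found in trajectory metadata; pass dt_ps explicitly"
                )
            dt_ps = float(dt_meta)

    sources = (str(structure_path),)
    if trajectory_path is not None:
        sources += (str(trajectory_path),)
    return TrajectorySystem(
        names=names,
        resids=resids,
        resnames=resnames,
        chain_ids=chain_ids,
        elements=elements,
        coords=frames,
        dt_ps=float(dt_ps),
        source_paths=sources,
    )


def split_chains(system: TrajectorySystem) -> dict[str, TrajectorySystem]:
    """Partition a system into one subsystem per chain (input atom order kept)."""
    order: list[str] = []
    for chain in system.chain_ids:
        if chain not in order:
            order.append(str(chain))
    return {
        chain: system.subset(np.flatnonzero(system.chain_ids == chain))
        for chain in order
    }


def select_atoms(
    system: TrajectorySystem,
    names: Sequence[str] | None = ("CA",),
    chains: Sequence[str] | None = None,
    resid_range: tuple[int, int] | None = None,
    allow_empty: bool = False,
) -> AtomSelection:
    """Resolve an atom predicate to ascending indices with residue grouping.

    The default predicate is one alpha-carbon per residue. ``resid_range``
    is inclusive on both ends (author numbering).
    """
    mask = np.ones(system.n_atoms, dtype=bool)
    parts: list[str] = []
    if names is not None:
        name_set = {str(n) for n in names}
        mask &= np.isin(system.names, list(name_set))
        parts.append("name " + "/".join(sorted(name_set)))
    if chains is not None:
        chain_set = {str(c) for c in chains}
        mask &= np.isin(system.chain_ids, list(chain_set))
        parts.append("chain " + "/".join(sorted(chain_set)))
    if resid_range is not None:
        lo, hi = resid_range
        mask &= (system.resids >= lo) & (system.resids <= hi)
        parts.append(f"resid {lo}-{hi}")
    predicate = " and ".join(parts) if parts else "all"

    indices = np.flatnonzero(mask)
    if indices.size == 0 and not allow_empty:
        raise EmptySelectionError(f"selection '{predicate}' matches no atoms")

    keys: list[tuple[str, int, str]] = []
    groups: list[list[int]] = []
    current: tuple[str, int] | None = None
    for idx in indices:
        ident = (str(system.chain_ids[idx]), int(system.resids[idx]))
        if ident != current:
            current = ident
            keys.append((ident[0], ident[1], str(system.resnames[idx])))
            groups.append([])
        groups[-1].append(int(idx))
    return AtomSelection(
        indices=indices,
        residue_keys=keys,
        residue_groups=[np.asarray(g, dtype=int) for g in groups],
        predicate=predicate,
    )


def _format_atom_name(name: str) -> str:
    name = str(name)
    # Names shorter than 4 chars are right-padded into columns 14-16 with a
    # leading blank in column 13, per the fixed-column convention.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _resolve_bfactors(
    system: TrajectorySystem,
    bfactors: Mapping[tuple[str, int], float] | Sequence[float] | np.ndarray | None,
) -> np.ndarray:
    if bfactors is None:
        return np.zeros(system.n_atoms)
    if isinstance(bfactors, Mapping):
        per_atom = np.zeros(system.n_atoms)
        for i in range(system.n_atoms):
            key = (str(system.chain_ids[i]), int(system.resids[i]))
            per_atom[i] = float(bfactors.get(key, 0.0))
        return per_atom
    values = np.asarray(bfactors, dtype=float)
    if values.shape == (system.n_atoms,):
        return values
    keys = system.residue_keys()
    if values.shape == (len(keys),):
        lookup = {(c, r): v for (c, r, _), v in zip(keys, values)}
        return _resolve_bfactors(system, lookup)
    raise RmsxError(
        f"bfactors must give one value per atom ({system.n_atoms}) or per residue "
        f"({len(keys)}), got shape {values.shape}"
    )


def write_pdb_frame(
    system: TrajectorySystem,
    frame_index: int,
    bfactors: Mapping[tuple[str, int], float] | Sequence[float] | None,
    path: str | Path,
    remarks: Sequence[str] = (),
) -> Path:
    """Write one frame as a fixed-column PDB with metric values as B-factors.

    Coordinates land in columns 31-54 (``%8.3f`` each) and B-factors in
    columns 61-66 (``%6.2f``), clamped to [0.00, 999.99]. ``bfactors`` may
    be per-atom (length ``n_atoms``), per-residue (length ``n_residues``,
    broadcast to all atoms of the residue), or a ``(chain, resid) -> value``
    mapping.
    """
    if not 0 <= frame_index < system.n_frames:
        raise RmsxError(
            f"frame_index {frame_index} out of range [0, {system.n_frames})"
        )
    per_atom = np.clip(_resolve_bfactors(system, bfactors), BFACTOR_MIN, BFACTOR_MAX)
    path = Path(path)
    frame = system.coords[frame_index]
    lines: list[str] = [f"REMARK {r}" if not r.startswith("REMARK") else r for r in remarks]
    for i in range(system.n_atoms):
        x, y, z = frame[i]
        lines.append(
            "ATOM  {serial:>5d} {name:4s} {resname:<4s}{chain:1s}{resid:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {elem:>2s}".format(
                serial=(i + 1) % 100000,
                name=_format_atom_name(system.names[i]),
                resname=str(system.resnames[i])[:4],
                chain=str(system.chain_ids[i])[:1] or "A",
                resid=int(system.resids[i]) % 10000,
                x=x,
                y=y,
                z=z,
                occ=1.0,
                bf=per_atom[i],
                elem=str(system.elements[i])[:2],
            )
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_multimodel_pdb(system: TrajectorySystem, path: str | Path) -> Path:
    """Write all frames as a multi-model PDB trajectory."""
    path = Path(path)
    chunks: list[str] = []
    for k in range(system.n_frames):
        chunks.append(f"MODEL     {k + 1:>4d}")
        frame = system.coords[k]
        for i in range(system.n_atoms):
            x, y, z = frame[i]
            chunks.append(
                "ATOM  {serial:>5d} {name:4s} {resname:<4s}{chain:1s}{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {elem:>2s}".format(
                    serial=(i + 1) % 100000,
                    name=_format_atom_name(system.names[i]),
                    resname=str(system.resnames[i])[:4],
                    chain=str(system.chain_ids[i])[:1] or "A",
                    resid=int(system.resids[i]) % 10000,
                    x=x,
                    y=y,
                    z=z,
                    occ=1.0,
                    bf=0.0,
                    elem=str(system.elements[i])[:2],
                )
            )
        chunks.append("ENDMDL")
    chunks.append("END")
    path.write_text("\n".join(chunks) + "\n")
    return path
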
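# rmsx

Time-windowed per-residue fluctuation analysis of molecular-dynamics
trajectories.

The trajectory's frame range is partitioned into equal consecutive windows
(trailing frames that do not fill a window are dropped) and a standard
per-residue RMSF is computed inside each window about the within-window mean
position. Concatenating the window-wise profiles yields a residues × time
matrix that shows *when* and *where* fluctuations occur. The package also
provides:

- **Shift maps** — per-residue Euclidean displacement from a reference frame,
  per frame (cumulative drift), with optional rigid superposition.
- **Per-residue lDDT time series** — preservation of short-range reference
  distances (CA atoms, 15 Å inclusion radius, 0.5/1/2/4 Å thresholds by
  default); insensitive to rigid-body motion.
- **Kabsch superposition** and per-frame RMSD series for alignment and
  context plots.
- **Exports** — long-format CSV of any metric matrix, and per-window PDB
  snapshots with the metric in the B-factor column plus a `REMARK` recording
  the shared color range.
- **Visualization** — residues × time heatmap PNG, an RMSD | heatmap | RMSF
  triple plot, and generated ChimeraX (`.cxc`) / VMD (`.tcl`) scripts that
  arrange the snapshots into a sequential "flipbook" with identical palette
  stops and value ranges across every output. Eight palettes (viridis,
  magma, plasma, inferno, cividis, mako, rocket, turbo) ship as packaged
  256-entry RGB tables.
- **Synthetic trajectories** — a generator with closed-form fluctuation
  statistics (Gaussian jitter σ → RMSF σ√3, sinusoid amplitude A → A/√2,
  events, drift, tumbling, 1–2 chains) used throughout the test suite.

Structure input is PDB; trajectories may be multi-model PDB, DCD, XTC, or
TRR (parsed via MDAnalysis).

## CLI

```bash
# generate a synthetic system, then analyze it
rmsx synth --seed 1 --residues 20 --frames 200 --out demo
rmsx run --structure demo/structure.pdb --trajectory demo/trajectory.dcd \
         --dt-ps 10 --slices 8 --out demo_run

# multi-chain systems: every chain plus the full complex
rmsx all-chains --structure complex.pdb --trajectory traj.xtc \
                --dt-ps 20 --frames-per-slice 4000 --out out

# companion metrics and window-size comparison
rmsx shiftmap --structure s.pdb --trajectory t.dcd --dt-ps 10 --out out
rmsx lddt --structure s.pdb --trajectory t.dcd --dt-ps 10 --out out
rmsx window-check --structure s.pdb --trajectory t.dcd --dt-ps 10 \
                  --candidates 4,8,16,32,64,128 --out out

# viewer scripts from a snapshot directory
rmsx flipbook --snapshots demo_run/A/snapshots --viewer chimerax
rmsx flipbook --snapshots demo_run/A/snapshots --viewer vmd
```

Per chain, `run`/`all-chains` write `chain_rmsx.csv` (long format:
`chain_id,residue_id,residue_name,slice_index,slice_start_ns,slice_end_ns,value`),
`rmsx_heatmap.png`, `snapshots/slice_NNN.pdb`, optionally `triple_plot.png`,
and a `manifest.json` with the resolved slice plan and package versions.
CLI frame numbers are 1-based inclusive; the API uses 0-based half-open
ranges.

Exactly one of `--slices N` / `--frames-per-slice K` selects the
partition; the remainder is dropped from the end and the plan (total frames
analyzed, equivalent time in ns) is echoed and logged.

## Library sketch

```python
from rmsx import (SyntheticSpec, build_system, select_atoms, plan_slices,
                  compute_rmsx, classic_rmsf, shift_map, lddt_series)

system = build_system(SyntheticSpec(n_residues=30, n_frames=500, sigma=0.3, seed=1))
sel = select_atoms(system)                       # one CA per residue
plan = plan_slices(system.n_frames, n_slices=10, dt_ps=system.dt_ps)
matrix = compute_rmsx(system, plan, sel)         # residues x 10 windows, Å
```
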
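# ionflux

Analysis toolkit for membrane ion-channel studies combining three stages:

1. **Trajectory geometry** (`ionflux.structures_io`, `ionflux.trajectory_metrics`)
   — multi-model PDB reading, atom-role classification, per-residue
   probe contact fractions (3.5 Å heavy-atom cutoff), ion coordination
   numbers (polar O/N/S within 2.5 Å), nearest-ion and inter-residue
   distance series, membrane hydrophobic thickness (phosphorus or
   ester-carbon leaflet averages), backbone-dihedral helix assignment,
   and Kabsch superposition RMSD.
2. **Constant-velocity pulling force profiles** (`ionflux.smd_profile`)
   — force-log parsing, pooling of repeated trials sorted by ion
   position, centered moving-average smoothing (501-point force window,
   101-point coordination window), peak extraction, mutant/wild-type
   peak ratios, and trial-count convergence curves.
3. **ATR-FTIR difference spectroscopy** (`ionflux.ftir`) — on-minus-off
   difference spectra, forward/backward cycle averaging, baseline-drift
   subtraction over band-free anchor windows, cation double differences,
   band-pair peak-minus-trough intensities, Hill binding fits
   (I(C) = A·Cⁿ/(K_dⁿ + Cⁿ)), and carboxylate ν_as−ν_s
   coordination-mode classification.

`ionflux.synthetic` generates every input class with known ground truth:
pseudo-lipid bilayers (324 POPE : 108 POPG), scripted ion-binding
trajectories, a 1-D overdamped-Langevin pulling surrogate over Gaussian
potentials, and Hill-structured FTIR spectra with drift and noise.
All generators are seed-deterministic and return `(data, ground_truth)`.

## CLI

One entry point with subcommands:

```sh
ionflux synth membrane --seed 1 --jitter-sd 0 --out mem/
ionflux thickness --pdb mem/membrane.pdb --out thickness.json

ionflux synth binding-traj --seed 2 --out bind/
ionflux contacts --pdb bind/binding.pdb --residues B:24 --probe ion --out contacts.tsv

ionflux synth smd --seed 3 --n-trials 10 --out smd/
ionflux smd-profile --logs smd/ --window 501 --out profile.tsv

ionflux synth ftir --seed 4 --out ftir/
ionflux ftir --manifest ftir/manifest.yaml --pair 1662:1648 --out fit.json

ionflux run --config config.yaml   # multi-stage run with manifest
```

A run config is YAML with keys `seed`, `outdir`, `stages`, `params`;
all analysis parameters default to the study's values (3.5 Å contact
cutoff, 2.5 Å coordination cutoff, windows 501/101, spring constant
6.16 kcal mol⁻¹ Å⁻², velocity 0.05 Å/ps, NaCl series
0.5–100 mM). Reruns with the same config and seed are byte-identical.

## Layout

```
src/ionflux/
  structures_io.py      # PDB I/O, roles, selections, TSV/JSON output
  trajectory_metrics.py # contacts, coordination, distances, thickness,
                        # helix assignment, Kabsch RMSD
  smd_profile.py        # force logs, pooling, smoothing, peaks, convergence
  ftir.py               # difference spectra, Hill fits, mode classification
  synthetic.py          # ground-truth generators for all input classes
  cli.py                # click CLI and pipeline orchestration
tests/                  # unit, property (hypothesis) and acceptance tests
scripts/acceptance.py   # acceptance-target recomputation
```
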
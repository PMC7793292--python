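# protasym

Analyses for probing conformational asymmetry in two-protomer protein
assemblies, built around coordinate ensembles (multi-model PDB), small-angle
scattering invariants, and dose-response activation fitting.

## What it does

- **structure_io** — multi-model PDB read/write (fixed-column subset),
  conjunctive atom selections, author residue numbering preserved.
- **synthetic_data** — generators for every input class the analyses
  consume: C2-symmetric two-protomer ensembles with independently hinged
  mobile domains and a two-state (open ≈ 6.9 Å / closed ≈ 4.9 Å) pocket
  coordinate; uniform bead spheres with closed-form scattering; noisy
  Hill-model activation curves. All are pure functions of (params, seed).
- **superposition** — Kabsch least-squares fitting and per-residue RMSF
  profiles after iterated mean-structure alignment.
- **vector_geometry** — per-frame polar coordinates (d, θ, φ) of an
  inter-domain anchor vector in a body-fixed frame, a mean-normalized
  per-frame asymmetry index ΔX = 100·⟨|X₁/X̄₁ − X₂/X̄₂|⟩, and helix
  hinge angles from principal segment axes.
- **pocket_metrics** — landmark atom-pair distance series and normalized
  distance populations; Shrake–Rupley accessible surface area with a
  configurable probe radius (default 2.8 Å, a ligand-sized probe) on a
  deterministic golden-spiral point lattice.
- **saxs_invariants** — Debye scattering profiles (histogram-accelerated),
  P(r) with Dmax, Rg via Guinier and via P(r), Porod volume with the
  MW ≈ Vp/1.7 rule, Kratky transform with a compactness flag, and reduced
  χ² between model and experimental profiles.
- **activation** — Hill-equation fitting in log10(EC50) with analytic
  standard errors, plus side-by-side comparison tables.
- **pipeline** — declarative YAML config orchestrating any subset of the
  stages with per-stage seed streams and a deterministic JSON report.

## CLI

```sh
protasym generate-ensemble --n-frames 500 --seed 1 --out ens.pdb
protasym rmsf --traj ens.pdb --align A:210-265:CA --target A
protasym vectors --traj ens.pdb --anchor-a A:230:CA --anchor-b A:359:CA \
    --body-frame A:210-265:CA
protasym asymmetry --traj ens.pdb \
    --anchor-a1 A:230:CA --anchor-b1 A:359:CA --body-frame1 A:210-265:CA \
    --anchor-a2 B:230:CA --anchor-b2 B:359:CA --body-frame2 B:210-265:CA
protasym pocket --traj ens.pdb --pair "A:360:CB;A:351:CG" \
    --sasa-residues A:351,360:CB,CG --probe 2.8
protasym saxs --model beads.pdb --profile exp.dat
protasym hill-fit --data curves.csv
protasym run --config run.yaml
```

Selections are `CHAIN:RESIDS:NAMES` with any field omitted (`A:210-265:CA`,
`A:360:CB`, `::CA`). Helix segments: `B:330-340,C:342-352,N:354-369`.

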
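# fdanet

Force distribution analysis (FDA) for detecting allosteric signalling
pathways in molecular systems. The pipeline monitors *pairwise
inter-atomic forces* rather than coordinates: forces are computed per
frame over all interaction types (bonds, angles, dihedrals, Coulomb,
Lennard-Jones), averaged over replica trajectories for two states
(ligand-free "apo" vs ligand-bound "holo"), differenced, and turned
into

* **punctual stress** — per-atom sums of absolute force differences,
* a **thresholded force-difference network** over residues, with a
  cutoff scan that keeps a consecutive path from the binding sites to
  the interdomain hinge while suppressing noise components,
* **hinge bending-angle profiles** (CA triplets, replica mean ± SD,
  quadrature-propagated differences),
* **hydrogen-bond occupancy** tables and least-squares superposition.

Because real multi-hundred-nanosecond MD ensembles are out of reach at
desk scale, the package ships a first-class synthetic benchmark: a
two-domain bead model with a *designed* binding-site→hinge force
pathway (stiffened springs + alternating charges + a charged ligand)
and a designed hinge-angle change, sampled by overdamped Langevin
dynamics. The generator's ground truth drives the recovery tests.

## Layout

| Module | Role |
| --- | --- |
| `fdanet.model_io` | domain types, PDB / extended-XYZ / topology I/O, units (internal kJ/mol/nm, reported pN) |
| `fdanet.pairforce` | per-frame pair forces, central-force decomposition of angle/dihedral terms, signed scalarization |
| `fdanet.fda_stats` | replica-first averaging, state differencing, punctual stress, convergence checks |
| `fdanet.force_network` | thresholded residue graphs, largest component, cutoff scan, pathway tracing |
| `fdanet.geometry` | bending angles, H-bonds, Kabsch superposition |
| `fdanet.synthetic_system` | two-domain benchmark generator + recovery scoring |
| `fdanet.pipeline` / `fdanet.cli` | YAML-driven orchestration and the `fdanet` command |

## CLI

Generate a synthetic bundle and run the full analysis on it:

```bash
fdanet synth --out demo --seed 1
fdanet run --config demo/config.yaml
```

`run` writes averaged force tables, the ΔF table, per-atom/per-residue
stress tables plus a stress-coloured PDB (B-factor column), the cutoff
scan, the edge list, a pathway report, angle and H-bond tables, and a
JSON manifest into `demo/results/`.

Individual stages are exposed as subcommands operating on CSV tables:

```bash
fdanet aggregate --topology demo/apo.top --trajectory demo/apo_rep1.xyz ... --out apo.csv
fdanet diff --state-a apo.csv --state-b holo.csv --out delta.csv
fdanet stress --delta delta.csv --topology demo/holo.top --out-prefix stress
fdanet scan --delta delta.csv --topology demo/holo.top --sources "4 8 11" --targets "30 32" --out scan.csv
fdanet network --delta delta.csv --topology demo/holo.top --cutoff 90 --out edges.csv
fdanet angles --topology demo/apo.top --trajectory demo/apo_rep1.xyz --triplet 28-30-32
fdanet hbonds --topology demo/apo.top --trajectory demo/apo_rep1.xyz --donors "3 4" --acceptors "30 32"
fdanet recover --delta delta.csv --topology demo/holo.top --truth demo/truth.json --cutoff 40
```

The custom topology dialect (`[atoms]/[bonds]/[angles]/[dihedrals]/
[exclusions]/[groups]`) is documented in
`src/fdanet/model_io/topology.py`.

## Conventions

* Signed scalar pair force: vector norm with positive = repulsive,
  negative = attractive; reported in pN (1 kJ/mol/nm = 1.660539 pN).
* Averaging is replica-first (mean of replica means; SD across
  replicas); a pair absent from a frame/state contributes zero.
* Residue network edges use the maximum spanning atom-pair |ΔF| with a
  strict cutoff inequality; default cutoff 90 pN.
* Atom and residue indices are 1-based everywhere user-facing.
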
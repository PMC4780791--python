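# permeon

Binding-site state analysis of single-file ion permeation through a channel
pore. The package turns per-frame 1-D ion coordinates along the pore axis into
binding-site occupancy states (S0 at the extracellular exit through S6, the
hydrated cavity), builds state-transition graphs with influx/efflux edge
flags, detects completed conduction events from ion-identity boundary
crossings (rejecting same-side "back-running"), classifies each event's
mechanism — **III-IV-III** (push: the replacement ion associates before the
outermost ion leaves, via a four-ion intermediate) vs **III-II-III** (pull:
the outermost ion dissociates first, via a two-ion intermediate) — and
computes single-channel currents with local block-bootstrap errors,
group free-energy differences, and intermediate-state lifetimes.

A kinetic Monte Carlo (Gillespie) generator of single-file hopping
trajectories with exact ground-truth event logs makes every stage testable
without MD data: discrete sites with hard-core exclusion, voltage bias,
well depths, nearest-neighbor knock-on repulsion, concentration-like entry
rates, and Gaussian positional jitter.

## Layout

| module | contents |
| --- | --- |
| `permeon.trajectory_io` | trajectory tables (TSV/CSV), pore-axis projection, equilibration trim, V = L_z·E |
| `permeon.site_model` | site thresholds (given or estimated from density minima), region assignment |
| `permeon.state_analysis` | per-frame binding states, transition graph, group tags (II/IIIr/IIIe/IV/V) |
| `permeon.conduction_events` | boundary events, conduction detection, mechanism classification, lifetimes |
| `permeon.kinetics` | currents, local block bootstrap, ΔG between groups, per-condition summary |
| `permeon.synthetic_data` | KMC generator, push/pull/inward/backrun regimes, fixture suite |
| `permeon.cli` | `permeon` command-line interface |

## CLI

```bash
# synthesize a trajectory with ground truth
permeon simulate --regime push --strength 9 --t-end 100 --seed 1 \
    --out traj.tsv --log-out truth.csv --sites-out sites.yaml

# inspect / stage by stage
permeon validate traj.tsv
permeon states  --traj traj.tsv --sites-config sites.yaml --out states.tsv
permeon graph   --traj traj.tsv --sites-config sites.yaml \
    --graphml-out graph.graphml --dot-out graph.dot
permeon events  --traj traj.tsv --sites-config sites.yaml \
    --events-out events.csv --conductions-out conductions.csv
permeon kinetics --traj traj.tsv --sites-config sites.yaml \
    --block-size 100 --n-boot 1000000 --seed 1 --out summary.json

# everything at once from a YAML config
permeon run --config run.yaml
```

A minimal `run.yaml`:

```yaml
traj: traj.tsv
outdir: out
sites_source: file      # default | file | estimate
sites_path: sites.yaml
t_cut_ps: 0.0
resting_count: 3
block_size_ps: 100.0
n_boot: 100000
seed: 1
```

Trajectory tables are tidy TSV/CSV with columns `frame,time_ps,ion_id,z`
(z in Å along the pore axis, increasing toward the extracellular side).
3-D input can be projected with `permeon project --points points.csv
--origin x,y,z --tip x,y,z --out traj.tsv`.

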
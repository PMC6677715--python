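# stochtissue

Multilevel stochastic simulation of pattern formation in growing
tissue: spatial-stochastic single cells (reaction–diffusion master
equation, RDME) coupled to an on-lattice, pressure-driven cell
population (discrete Laplacian cell mechanics, DLCM), communicating
through junctional and protrusion-mediated Notch–Delta signaling.

## The problem

Lateral inhibition through the Notch pathway turns fields of identical
epithelial cells into precise salt-and-pepper, spot or stripe patterns:
a cell that commits to the high-Delta fate suppresses that fate in the
cells it touches. Direct membrane contact alone produces the classical
alternating pattern; signaling through cellular protrusions that reach
past nearest neighbors produces the sparser motifs seen, for example,
in the bristle pattern of the fly notum. Simulating this faithfully in
a *growing* tissue requires three things at once: molecular noise at
realistic copy numbers inside each cell, cell-to-cell signal geometry,
and population mechanics — each in continuous time. `stochtissue`
implements all three layers and their coupling with Gillespie-style
event-driven samplers, for computational modelers who want
population-scale consequences of single-cell stochastic pathways.

## The model

Per cell, non-dimensional Notch/Delta/reporter dynamics with trans- and
cis-interactions and Hill regulation:

    n' = β_n − ⟨d_in⟩ n / k_t − d n / k_c − n
    d' = β_d / (1 + r^m) − d ⟨n_in⟩ / k_t − d n / k_c − d
    r' = β_r (⟨d_out⟩ n)^s / (k_rs + (⟨d_out⟩ n)^s) − r

with signals summed over junctional neighbors J(i) and protrusional
contacts P(i) under weights `[w_a, q_a, w_b, q_b]`. The stochastic
interpretation reads concentrations as molecule counts at volume
Ω = 400 and simulates the nine implied reaction channels exactly, with
cell-to-cell signals frozen over adaptive time chunks
`dτ = 0.05 ‖x‖/‖f(x)‖`. Inside a cell, space is resolved by ~40
dual-mesh voxels with diffusion as jump reactions (Next Subvolume
Method). The population layer solves `−Lp = 1{u=2}`, `p|∂ = 0` for the
cellular pressure on the occupied lattice and converts edge currents
`(e/d)(p_i − p_j)` into movement rates; growth is nutrient-limited and
every population event is recorded in a replayable log. See
`docs/methods.md` for the full account.

## Worked example

Stochastic pattern formation on a static 6×6 hexagonal grid with
isotropic protrusions of length 3.5 cell radii:

```python
import numpy as np
from stochtissue import (PathwayParams, ProtrusionSpec,
                         build_contact_graph, build_hex_lattice,
                         ssa_population)
from stochtissue.pathway import random_initial_counts

params = PathwayParams()          # reference parameter set
lattice = build_hex_lattice(6, 6)
graph = build_contact_graph(lattice, ProtrusionSpec(length=3.5),
                            params.weights)
rng = np.random.default_rng(1)
initial = random_initial_counts(lattice.n_cells, params, rng)
times, traj = ssa_population(initial, graph, params, t_end=30.0,
                             seed=rng,
                             output_times=np.array([4.0, 20.0, 30.0]))
for t, snap in zip(times, traj):
    D = snap[:, 1]
    high = D > max(D.max() / 10.0, 1)
    print(f"t={t:5.1f}  high-Delta cells: {high.sum():2d}/36  "
          f"max D={D.max():6d}  median D={int(np.median(D))}")
```

prints

```
t=  4.0  high-Delta cells:  5/36  max D=  4861  median D=0
t= 20.0  high-Delta cells:  7/36  max D= 58664  median D=0
t= 30.0  high-Delta cells:  7/36  max D= 57311  median D=0
```

Delta collapses to zero in most cells while a sparse minority (here
7/36) locks into the high-Delta fate — the protrusion-widened
inhibition range makes the pattern sparser than the classical
nearest-neighbor checkerboard, and the per-cell Delta distribution is
strongly bimodal (the high/low ratio exceeds four orders of
magnitude). The same experiments are available from the shell:

```
stochtissue growth  --preset growth --seed 1 --out runs/growth
stochtissue coupled --preset coupled-spots --seed 1 \
    --events runs/growth/events.jsonl --out runs/spots
```

which write a replayable population event log, per-snapshot grid
tables and a `time,cell_id,N,D,R` trajectory CSV.

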
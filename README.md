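# nridyn

Neural relational inference (NRI) for learning latent residue–residue
interaction graphs from molecular-dynamics-style trajectories, with
downstream allosteric-pathway extraction and mutation-stability scoring.

## Who this is for

Structural bioinformaticians and molecular modellers who have multi-frame
coordinate data (an MD trajectory reduced to one point per residue, or any
interacting-particle trajectory) and want to know **which pairs interact**,
**which routes carry signal** between a distal site and an active site, and
**how mutations shift stability** — without hand-picking contacts or
covariance cutoffs.

## The model

A trajectory of N nodes, `x_i^t` (position + velocity per axis, 6 features),
is modelled as a variational autoencoder over an unobserved discrete
interaction graph `z` with K = 4 edge types per ordered pair (type 1 is a
hard-coded "nonedge" that carries no decoder message). Training maximizes
the ELBO

    L(Φ, θ) = E_{q_Φ(z|x)}[log p_θ(x|z)] − KL(q_Φ(z|x) ‖ p(z)),

where the encoder `q_Φ` is a message-passing network over the fully
connected graph (two node→edge rounds of 2-layer perceptrons), sampling uses
the Gumbel-softmax relaxation `z_ij = softmax((log q_ij + g)/τ)`, and the
decoder predicts `μ_j^{t+1} = x_j^t + f_out(GRU([Σ messages, x_j^t], h_j^t))`
under a fixed-variance Gaussian likelihood. The prior is
(0.91, 0.03, 0.03, 0.03), favouring sparse graphs.

From the learned posterior the package derives: a directed interaction
matrix (`w_ij = 1 − P(nonedge)`), domain/block aggregation, node weights,
shortest and k-shortest (suboptimal) source→sink pathways under
`cost = −log w`, betweenness centralities, and the pairwise free-energy
score `E_z` (edge weights summed over residue pairs within a 12/15 Å
reference distance) whose mutant-minus-wild-type difference ΔG_Z is
correlated against experimental ΔΔG with a two-sided Pearson test
(df = n − 2, signed R², Fisher-z CI).

A spring-system simulator with known ground-truth graphs (and a driven
chain with a planted communication pathway) makes every stage testable
without MD data; see `docs/methods.md` for the model, benchmark conditions
and their rationale.

## Worked example

Simulate a 5-node spring benchmark, train, and read off the learned edges:

```sh
nridyn simulate --nodes 5 --steps 7500 --seed 7 --out run/sim
nridyn train --trajectory run/sim/trajectory.tsv --steps 1500 \
             --epochs 60 --seed 7 --out run/model
nridyn infer-edges --model run/model/model.npz \
                   --trajectory run/sim/trajectory.tsv --steps 1500 \
                   --out run/edges
nridyn pathways --matrix run/edges/interaction_matrix.tsv \
                --sources 0 --sinks 4 --k-paths 2 --out run/paths
```

The four commands print:

```
wrote run/sim/trajectory.tsv (5 nodes, 7500 frames, 4 true edges)
final valid MSE 0.00813; test MSE 0.00814; VSD 0.0040; wrote run/model/model.npz
wrote run/edges/interaction_matrix.tsv (total weight 10.352)
2 paths; wrote run/paths/paths.json
```

Reading the numbers: the held-out reconstruction MSE (0.008 in normalized
units) and the VSD of 0.004 (squared deviation between true and
reconstructed per-node RMSF profiles) say the trained decoder reproduces
the held-out dynamics closely. `run/edges/interaction_matrix.tsv` holds the
learned weight `w_ij = 1 − P(nonedge)` per ordered pair; for this seed the
strongest learned edges (w > 0.7) include the true couplings 1–2 and 0–3↔4
region of the ground-truth graph written to `run/sim/ground_truth.tsv`.
`run/paths/paths.json` lists the two cheapest 0→4 routes under
`cost = −log w`: the direct learned edge (cost 0.44) and the suboptimal
detour 0→3→4 (cost 0.74).

## Library use

```python
from nridyn import (ModelConfig, simulate_springs, train,
                    edge_recovery_accuracy)
from nridyn.synthetic import springs_study_config, to_raw_trajectory
from nridyn.trajectory import featurize, make_windows, subsample

features, graph = simulate_springs(springs_study_config(seed=1))
raw = subsample(to_raw_trajectory(features), 1500)
splits = make_windows(featurize(raw), window_length=10, stride=1, seed=1)
params, log = train(splits, ModelConfig(), epochs=60, seed=1)
print(edge_recovery_accuracy(params, splits.test, graph))
```

Protein input works the same way: `load_coordinates("traj.pdb")` extracts
one Cα per residue from a multi-model PDB, `subsample(raw, 50)` applies the
50-step sampling menu, and residue numbers survive as node labels for
`--sources`/`--sinks` selections.

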
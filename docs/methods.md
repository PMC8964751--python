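# Methods

## The model

`nridyn` implements neural relational inference (NRI) for trajectories of N
point nodes (one C-alpha per residue for protein input).  The generative
picture: an unobserved interaction graph z assigns every ordered node pair
(i, j), i != j, one of K discrete edge types; given z, the trajectory evolves
under pairwise influences.  The model is a variational autoencoder over z
trained by maximizing the ELBO

    L(Phi, theta) = E_q[log p_theta(x | z)] - KL(q_Phi(z | x) || p(z)),

with a factorized categorical posterior q per pair.

**Encoder.**  Each node's whole windowed trajectory (T steps x 6 features:
position and finite-difference velocity per axis) is embedded by a 2-layer
perceptron; two rounds of node-to-edge message passing with one edge-to-node
aggregation in between (sum over incoming pairs, self-pairs excluded)
produce K logits per ordered pair; a softmax yields the posterior.  All maps
are 2-layer perceptrons with ELU activations and shared weights, making the
encoder permutation-equivariant (a property the tests assert).

**Sampling.**  Edges are drawn with the Gumbel-softmax relaxation,
`z_ij = softmax((log q_ij + g)/tau)`, `g ~ Gumbel(0,1)` i.i.d., so the
discrete choice stays differentiable; as tau -> 0 samples approach one-hot.

**Decoder.**  A recurrent decoder with one GRU per node (shared weights).
At each step, per-pair messages are computed from the *hidden* states of
sender and receiver by per-edge-type 2-layer perceptrons, weighted by the
sampled z_ij and summed over types and incoming pairs.  Edge type 1 is the
hard-coded nonedge: it has no message function at all, so "no interaction"
is structural, not learned.  The GRU consumes [aggregated message, input]
and the predicted mean is the residual form mu_j^{t+1} = x_j^t +
f_out(h_j^{t+1}).  During training the decoder feeds its own mean back for
`prediction_steps` steps before resynchronizing with the true input;
forcing multi-step rollout is what makes inter-node information valuable —
with per-step teacher forcing, single-node extrapolation is too easy and
the edge latents carry no benefit.

**Loss.**  Gaussian reconstruction with fixed variance sigma^2 (sum over
nodes and steps 2..T of ||x - mu||^2 / 2 sigma^2) plus the categorical KL of
the posterior against the edge-type prior.  The default prior is
(0.91, 0.03, 0.03, 0.03): nonedge-heavy to favor sparse graphs; a uniform
prior is available (`ModelConfig.uniform_prior()`), in which case the KL
reduces to sum(log K - H(q)) per pair — an identity the tests check to
1e-10.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| K (`n_edge_types`) | 4 | one structural nonedge + 3 unordered interaction types |
| prior | 0.91 / 0.03 x3 | sparsity-favoring; uniform selectable |
| tau | 0.5 | Gumbel-softmax temperature; no annealing |
| sigma^2 | 1e-2 | output variance on [-1,1]-normalized data; sets the reconstruction/KL balance — much smaller values drown the sparsity pressure, much larger ones collapse the posterior to all-nonedge |
| hidden_dim | 32 | width of every embedding/message map |
| prediction_steps | 10 | rollout length between teacher-forcing resyncs |
| window_length | 10 | with the default step interval, one window spans roughly one oscillation period of the benchmark springs |
| lr / decay | 5e-3 Adam, x0.995 per epoch | |
| warmup_epochs | 3 | see below |

**Decoder warm-up.**  Joint training from a cold start is bistable: random
message functions initially *hurt* reconstruction, so the first gradient
steps push every pair to nonedge, after which the message functions receive
no gradient and the posterior never recovers.  For the first
`warmup_epochs` epochs the decoder is therefore trained with edges sampled
from the *prior* (the encoder receiving no gradient); once the message
functions are informative, joint ELBO training proceeds.  Checkpoint
selection (best held-out reconstruction MSE) only considers post-warm-up
epochs.

## Synthetic benchmark systems

**Springs.**  Point masses coupled by Hookean springs (F = -k(r_i - r_j))
on an Erdos-Renyi graph, integrated with velocity-Verlet (symplectic; the
noiseless system's energy drift is bounded below 1% over 10,000 steps at
the default dt = 0.1, a test asserts this).  Initial positions uniform in a
+-1 box, initial velocities Gaussian (sigma = 0.5) shifted to the
center-of-mass frame.  The canonical recovery study
(`springs_study_config`) adds a weak harmonic trap (k_trap = 0.1) — the
smooth analogue of the bounding box of classic relational-inference
benchmarks — because without it disconnected components drift apart
ballistically and, after normalization, every trajectory looks ballistic
and edges carry no predictive signal.  Trajectories are integrated for
7,500 frames and subsampled to 1,500 steps (interval 0.5 time units,
roughly 1/9 of the pair oscillation period): coarse enough that a node's
own history cannot explain its motion, fine enough to stay below Nyquist.

Observation noise, when enabled, is additive Gaussian on positions after
integration — measurement noise, not a thermostat.  The study condition
keeps it on (0.05 length units, a few percent of the motion amplitude):
one *noiseless* orbit of a small linear system is a degenerate inference
problem — the recurrent decoder can memorize each node's quasi-periodic
signal and the posterior never needs the coupling — whereas jittered
coordinates force the model to explain motion through the shared structure,
as with real trajectory data.

**Planted pathway.**  A linear chain 0-1-...-(n-1) with the same
zero-rest-length Hookean physics as the spring benchmark (every mode
linear and isotropic), plus an anchor drive on node 0: the anchor moves
along x with a broadband, seeded multi-sine signal (8 components, random
phases, frequencies in 0.3-1.2 sqrt(k/m) — inside the chain's propagation
band).  A broadband drive matters because a pure sinusoid settles into a
steady state that every node can extrapolate from its own history, leaving
the edges with nothing to explain.  Free chain modes are excited by random
initial velocities scaled by `initial_velocity_scale`; `damping` adds
viscous drag (its 0.05 default keeps a purely driven chain bounded and the
propagation visibly directed, which is what the positive-lag
cross-correlation test demonstrates).  With zero amplitude and zero
initial velocities the chain stays exactly at rest.  The recovery study
(`chain_study_config`) instead runs undamped so the free modes persist,
with a weak trap (0.02), unit velocity scale, and a coarser step interval
(1.0 time unit; the chain's internal modes are softer than a dense random
graph's, so a window must span longer physical time).  The ground-truth
allosteric pathway from node 0 to node n-1 is the chain itself.

## Featurization choices

* Velocity at step t is (pos_t - pos_{t-1}) / dt; the first step copies the
  second rather than introducing a spurious rest frame.
* Normalization centers and scales positions per axis into [-1, 1], with a
  floor: an axis whose extent falls below 20% of the widest axis keeps the
  floored scale instead of being stretched to full range.  Rescaling a
  near-degenerate axis (e.g. a chain moving mostly along x) would amplify
  pure measurement noise into order-one features and poison training.
  Velocities share the per-axis factors (not the shift); the transform is
  recorded and invertible to 1e-10.
* Train/valid/test splits are chronological, not random: trajectory frames
  are autocorrelated and random splits would leak test information into
  training.
* Frames are not rotationally/translationally superposed before
  featurization by default; superposition is out of scope for the toy
  systems and deliberately left to upstream MD tooling for protein input.
* Subsampling uses nearest-uniform selection: frame j of S kept frames is
  round(j * F / S) of F stored frames, always including frame 0 (5,000
  frames at 50 steps -> every 100th frame; at 20 steps -> a 250-frame
  interval).

## Downstream analyses

* **Interaction matrix.**  The K-type posterior collapses to one directed
  scalar weight per pair; default w_ij = 1 - P(nonedge), which is additive
  over non-null types and conserves total weight under block aggregation
  (sum rule; mean available).  Directionality is kept because the influence
  of i on j and of j on i are separate latents; undirected analyses
  symmetrize with max(w_ij, w_ji).
* **Pathways.**  Retained edges (w >= threshold, default 0.5) get cost
  -log w, so a path's cost is the negative log product of its edge weights
  — the most probable chain of interactions is the shortest path.  1/w is
  available as an alternative.  k-shortest loopless paths (Yen semantics
  via networkx `shortest_simple_paths`), equal-cost ties broken
  lexicographically; per-node path frequencies; betweenness centrality on
  the cost-weighted digraph, normalized to [0, 1].  Both the fixed-k and a
  cost-tolerance notion of "suboptimal" are expressible (k paths, filter by
  cost).
* **Stability scores.**  E_z sums learned-edge weights over ordered pairs
  whose reference C-alpha distance (from a single reference structure,
  never per-frame) is below a cutoff (12 or 15 Angstrom conventionally);
  Delta G_Z = E_z(variant) - E_z(WT).  The Pearson correlation against
  experimental unfolding Delta Delta G reports a *signed* R^2 (the sign of
  r carried onto r^2, so anticorrelation is visible), the two-sided p with
  df = n - 2, and a 95% CI mapped from the Fisher z interval on r.  The
  unsigned R^2 is also emitted.  Only trends are meaningful: absolute free
  energies are out of scope.
* **VSD.**  The reconstruction-quality scalar compares per-node RMSF
  profiles of actual vs reconstructed trajectories; the working definition
  here is the mean over nodes of squared RMSF differences (symmetric, zero
  iff profiles match, lower is better).  It is isolated in one function
  (`vsd_from_rmsf`) so an alternative definition can be swapped in without
  touching callers.

## Known limitations

The planted-pathway chain is substantially harder for this model family
than the random spring benchmark, and the pipeline does not reliably
recover it end to end at desk scale.  Two failure modes, both reproducible
and now understood, are worth knowing about:

* **Weak edge payoff on sparse line topologies.**  Controlled probes that
  train the decoder alone with ground-truth edges versus no edges show the
  chain's motion is only modestly better predicted with edges (held-out
  MSE ratio about 1.1-1.3) compared with the random-graph benchmark (about
  1.6).  When the payoff is this small, joint ELBO training sometimes
  settles into the all-nonedge optimum despite the decoder warm-up.
* **Shortcut edges from message latency.**  The recurrent decoder computes
  messages from *hidden* states, so neighbour information arrives one step
  late.  On a slowly-mixing chain, a spurious next-nearest edge (i, i+2)
  genuinely improves prediction by bypassing that latency, and the prior's
  sparsity pressure does not remove it: runs that recover every true chain
  edge strongly also keep strong 2-hop shortcuts, and the extracted
  minimum-cost path can skip a node.  Denser random graphs mask the effect,
  which is why graph recovery succeeds there.

Practical consequence: on near-linear interaction topologies, treat the
learned edge map as a candidate set and the extracted shortest paths as
hypotheses to check against k-shortest alternatives (`shortest_paths` with
k > 1) rather than as a point estimate.

## What the synthetic benchmarks do and do not show

Passing the spring and chain studies shows the pipeline can (i) recover a
planted interaction graph from dynamics alone at the stated conditions,
(ii) beat the no-edge-latent ablation on held-out prediction, and (iii)
recover a planted communication pathway end to end.  The toy systems are
linear, noise-free (by default), and tiny; they say nothing about force
fields, solvent, conformational heterogeneity, or the time scales of real
allosteric transitions.  Protein-scale claims require real MD input.

## Reproducing protein-scale results

The file-based pipeline (multi-model PDB -> C-alpha extraction ->
subsampling to the 10..100-step menu -> training -> VSD / edge maps /
pathways / stability scores) is the same code path exercised by the tests
on synthetic data.  Published MD trajectory archives of two-domain
allosteric proteins (a WW/PPIase isomerase is the classic case) can be fed
through `nridyn featurize` and `nridyn train` at 50 sampling steps to
attempt protein-scale VSD values; note that published VSD figures for such
systems depend on an exact deviation formula and training hyperparameters
that are rarely fully specified, so agreement beyond qualitative level
carries definitional uncertainty.  A
step interval of about 20 ns of simulated time per step is the recommended
operating point; the CLI warns when the implied interval exceeds a tenth of
the declared simulation span.

## Numerical details and edge cases

* All training math runs in float32 on a small reverse-mode autodiff core
  (`nridyn.autodiff`), gradient-checked against central finite differences
  op by op and end to end through the Gumbel path.
* Training is bit-reproducible given the seed: initialization, Gumbel
  draws and batch order all derive from it.
* Degenerate inputs fail loudly: unstable integration names the step,
  missing C-alpha names residue and model, empty splits name the split,
  non-finite losses name the epoch.
* Equal-cost path ties are broken lexicographically; `0 log 0 = 0` in the
  KL; a prior with zero mass where the posterior has support raises.
* The problem sizes in the test suite and acceptance script (5-6 nodes,
  ~1,200 training windows, tens of epochs) were chosen as the smallest
  study at which the recovery phenomena are stable and fast to verify.
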
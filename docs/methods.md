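# Methods

## Model

`sornseq` simulates a self-organizing recurrent network (SORN) of binary
threshold units learning symbolic movement sequences.  The reservoir has
`N_E = 300` excitatory and `N_I = 0.2 N_E = 60` inhibitory units.  Excitatory
units are sparsely and randomly recurrently connected (each possible directed
E→E synapse exists independently with probability `p_connect = 0.1`; no
self-connections; rows with no incoming synapse are redrawn so the
normalization below stays defined).  Connections between the excitatory and
inhibitory populations are all-to-all.  All weights are drawn uniformly from
[0, 1] and row-normalized so every unit's incoming weights sum to one.

At discrete time t, with binary states x(t) (excitatory) and y(t)
(inhibitory),

    x_i(t+1) = Θ( Σ_j W^EE_ij x_j(t) − Σ_k W^EI_ik y_k(t) + v_i(t) − T^E_i(t) )
    y_i(t+1) = Θ( Σ_j W^IE_ij x_j(t+1) − T^I_i )

with strict thresholds (a unit receiving drive exactly equal to its threshold
stays silent) and the inhibitory update reading the *new* excitatory state.
Each input symbol drives a dedicated, non-overlapping group of
`n_input_per_symbol = 10` excitatory "input units" with v = 1.

Three plasticity rules act on the excitatory sub-network, in a fixed per-step
order (state update → STDP → clip/normalize → intrinsic plasticity):

* **STDP** (rate `η_STDP = 1e-4`): ΔW^EE_ij = η (x_i(t) x_j(t−1) −
  x_i(t−1) x_j(t)), applied only to existing synapses, clipped at zero.
  Synapses can be driven all the way to zero but are never created.
* **Synaptic normalization**: every incoming E→E weight row is rescaled to
  sum one at every step.  A row whose weights are all zero is left unchanged
  with a warning.
* **Intrinsic plasticity** (rate `η_IP = 0.002`): T^E_i ← T^E_i +
  η_IP (x_i(t) − H_IP), unclipped, driving each unit's long-run rate to the
  target `h_ip`.  Thresholds may rise without bound, which is what silences
  over-driven input units late in training.

`W^EI`, `W^IE`, and the inhibitory thresholds are fixed after initialization.

**The target rate `h_ip` is the one model constant with no published value.**
The default is 0.1, consistent with the sparse firing this model family is
known for; all quantitative statistics below (mutual information, cluster
composition, switch angles, interference magnitudes) shift with it.

## Readout

A linear layer maps the reservoir state to one output unit per symbol; the
winner-take-all output (argmax, ties to the lowest index) is the predicted
next sequence element.  The weights are trained at every training step by the
delta rule (rate `μ = 2e-5`, gradient of the squared output−target error) and
frozen during test blocks.  The readout reads the *non-input* excitatory
units by default: input units carry the current symbol deterministically, so
including them reduces prediction to a static symbol lookup that neither
improves with sequence learning nor degrades under interference — with them
included, every training schedule tests at near-zero error and the
blocked-versus-interleaved contrast disappears.  The architecture also wires
the output layer to the (non-input) reservoir units.  Set
`readout_on_input_units=True` to include them.

## Tasks and schedules

* Arm-movement task: two 20-element sequences sharing 12 of 20 positions;
  positions 1–4 are lead-in context symbols (A1–A4 vs B1–B4), the rest encode
  target position and movement direction jointly as distinct symbols.
* Finger-tapping tasks: 8-button sequence pairs differing at buttons 4&5 or
  4&7.
* Generated families: `generate_task_set(length, similarity, n_tasks)` draws
  a random set of `similarity × length` positions that carry symbols shared
  by *all* tasks; every other position gets a symbol unique to one task, so
  each pairwise similarity (one minus normalized Hamming distance) equals the
  requested value exactly.
* Schedules partition 200 trials per task into n blocks (3 = fully blocked …
  600 = one trial per block), block order randomized for interleaved
  schedules.  Block counts that do not divide evenly (e.g. 50 over 3 tasks)
  use nominal-size blocks plus one remainder block per task, conserving
  per-task trial totals.
* The readout target at each step is the next element of the current word;
  the word-final transition (into the next, unpredictable word) is flagged
  and excluded from error statistics.

Tests present 20 words per sequence with plasticity and readout frozen, each
starting from a copy of the end-of-training dynamic state, so test order is
irrelevant (the simulated analogue of counterbalancing).

## Analysis statistics

* **Separability** (the reaction-time proxy; higher = better): the sum of all
  ordered pairwise Euclidean distances between the reservoir states inside a
  window of one word length, excluding input units.
* **Clustering**: agglomerative clustering (Euclidean metric, average linkage
  by default) of the internal states — input units excluded, consistent with
  the separability state definition — into exactly 20 clusters; reported are
  the mean number of distinct input conditions (symbol × position) per
  cluster and the mean share of each cluster's dominant condition.  The
  alternative reading of the per-condition share (mean share of each
  *contributing* condition) is reported alongside.
* **Mutual information**: per neuron, between the binary response and the
  position-in-word (20 equiprobable conditions), from the empirical joint
  over one 20-word block.  All 300 units are included (input units are part
  of the published per-neuron MI analyses).  Natural logarithm by default —
  the defining equations are written with an unsubscripted log — with
  `base=2` available.
* **Selectivity index**: d = (k − Σ rates / max rate)/(k − 1) over input
  conditions; 0 = unselective, 1 = responds to a single condition; undefined
  (NaN) for silent units.
* **Weight trajectories**: incoming E→E weight vectors as points in N_E
  dimensions; distance from the initial vector per snapshot; direction change
  at a schedule switch as the angle between the displacement over the 1600
  steps before and after the switch (units with a zero displacement on either
  side are excluded); PCA of the pooled snapshots for visualization.

## Experiment protocols and effect measures

* Equal training (`run_panzer_exp1`): S1 for 400 words (8000 steps), then S2
  for 400 words; controls train a single sequence.  Doubled training
  (`run_panzer_exp2`): 800 S1 words before the same S2 phase.
* Finger tapping (`run_koedijker`): S1 then S2, 200 words each; per-position
  error over the first 20 trials of each sequence quantifies button-specific
  proactive facilitation (err_S1 − err_S2 at each target position).
* Blocked vs interleaved (`run_blocked_vs_interleaved`): three disjoint
  8-element sequences, 200 trials each, in 3 contiguous blocks or fully
  random single-trial interleaving.
* Similarity × schedule grid: anterograde effect = error over the first 10
  S1 training trials minus the first 10 S2 trials (positive = facilitation);
  retrograde effect = error over the last 5 S1 training trials minus the last
  5 S1 test trials after all training (positive = facilitation, negative =
  interference).
* Robustness: the equal-training protocol re-run for p_connect ∈
  {0.05, 0.1, 0.15} and N_I/N_E ∈ {0.1, 0.2, 0.4}.

## Problem sizes and numerical choices

All headline statistics are computed at full network size (300 units) over 10
random initializations; the full 8 × 9 similarity-×-schedule grid with 40
repetitions per cell is available through the library and CLI, while the test
suite checks the sign pattern on the grid's four corner cells (similarity
{0, 0.875} × {3, 600} blocks) with 10 repetitions, and the robustness sweep
uses 10 seeds per setting — the package's choice of statistically sufficient
desk-scale replication.  One global seeded generator per run feeds
initialization and schedule randomization; identical configuration and seed
reproduce every trajectory bit for bit.  The estimator's inner loop exploits
state sparsity (incremental STDP blocks, renormalization of only the rows
whose sums changed) and is verified against the reference composite step to
within floating-point accumulation order on short runs.

## What the simulations do and do not show

The network reproduces, under one parameter set: strong proactive
facilitation when a similar sequence was learned first; button-specific
facilitation that spares changed movements; retroactive interference in test
error rates, strongest for blocked schedules and absent under interleaving;
and the interaction surface of schedule × similarity in the anterograde and
retrograde effects.  Two published quantitative patterns do **not** reproduce
under `h_ip = 0.1`: the separability proxy saturates after full training, so
retroactive interference visible in error rates does not register as reduced
tested separability of the first sequence; and the direction change of weight
vectors at the switch comes out *larger* (not smaller) after doubled first
-sequence training, although the within-run structure (angles anticorrelated
with displacement magnitude, shrinking no-switch baseline angles from ~39° to
~12° across training) matches the published geometry.  Absolute mutual
-information and cluster-composition values likewise shift with `h_ip` and the
log base; the robust, reproducible facts are the orderings (MI: first block <
ablated < last block; clustering: conditions per cluster shrink and dominant
shares grow with training).

These are simulations of symbolic next-element prediction; no kinematics,
reaction-time distributions, or trial-to-trial human variability are modeled,
and the synthetic task generator enforces exact symbol-level similarity, not
the graded motor similarity of real movement sequences.
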
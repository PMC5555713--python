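# sornseq

Why does learning a second movement sequence sometimes build on the first
(facilitation, transfer) and sometimes damage it (proactive and retroactive
interference)?  `sornseq` is a simulator for studying that question with a
self-organizing recurrent network (SORN): a sparse network of binary
threshold units whose recurrent connectivity and excitability are shaped
online by three local plasticity rules, driven by symbolic movement
sequences and read out by a winner-take-all linear layer that predicts the
next sequence element.  It is aimed at computational-neuroscience work on
motor sequence learning, practice-schedule effects (blocked vs interleaved
training), and task-similarity effects.

## Model

A reservoir of N_E = 300 excitatory and N_I = 60 inhibitory binary units
evolves in discrete time:

    x_i(t+1) = Θ( Σ_j W^EE_ij x_j(t) − Σ_k W^EI_ik y_k(t) + v_i^U(t) − T^E_i(t) )
    y_i(t+1) = Θ( Σ_j W^IE_ij x_j(t+1) − T^I_i )

Each input symbol drives its own group of 10 input units (v = 1).  Three
plasticity rules act on the excitatory sub-network at every step:

* STDP:  ΔW^EE_ij = η_STDP (x_i(t) x_j(t−1) − x_i(t−1) x_j(t)),  η_STDP = 10⁻⁴
* synaptic normalization:  W^EE_ij ← W^EE_ij / Σ_j W^EE_ij
* intrinsic plasticity:  T^E_i ← T^E_i + η_IP (x_i(t) − H_IP),  η_IP = 0.002

A linear readout over the non-input reservoir units, trained online by the
delta rule (μ = 2·10⁻⁵), predicts the next element through winner-take-all.
Separability — the sum of pairwise Euclidean distances between the reservoir
states within one word, input units excluded — serves as the performance
proxy for reaction times; the readout error rate is the second performance
measure.  See `docs/methods.md` for the full account, defaults and caveats.

## Worked example

Train the network on the two 20-element arm-movement sequences (S1 for 400
words, then S2 for 400 words) and look at facilitation and interference:

```python
import numpy as np
from sornseq import SornSequenceLearner, TrainingSchedule, canonical_panzer_tasks
from sornseq.metrics import separability_per_word

tasks = canonical_panzer_tasks()
schedule = TrainingSchedule(blocks=[("S1", 400), ("S2", 400)],
                            test_blocks=[("S1", 20), ("S2", 20)])
model = SornSequenceLearner(record_states=True, random_state=0)
model.fit(tasks, schedule=schedule)

sep = separability_per_word(model.training_record(), 20)
print("separability, first 20 S1 words :", round(sep[:20].mean(), 1))
print("separability, first 20 S2 words :", round(sep[400:420].mean(), 1))

errors = model.trial_errors("test")
for task, err in errors.groupby("task")["error_rate"].mean().items():
    print(f"test error {task}: {err:.3f}")
```

```
separability, first 20 S1 words : 542.2
separability, first 20 S2 words : 1983.0
test error S1: 0.579
test error S2: 0.211
```

Separability over the first 20 words of S2 training (≈ 1983) is far higher
than at the equivalent point of S1 training (≈ 542): having learned S1
facilitates S2 from its first trials (proactive facilitation).  At test,
after S2 training, the earlier sequence S1 is predicted much worse (0.58
error) than the later S2 (0.21): learning S2 partially overwrote the memory
of S1 (retroactive interference).

The experiment battery lives in `sornseq.experiments`
(`run_panzer_exp1/2`, `run_koedijker`, `run_blocked_vs_interleaved`,
`run_similarity_schedule_grid`, `robustness_sweep`), and a CLI wraps it:

```bash
sornseq run --experiment blocked-vs-interleaved --seeds 0..9 --out results/bvi
sornseq validate-config config.yaml
```

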
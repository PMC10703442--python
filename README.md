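# seqprev

Analysis of how frontal-cortical ensemble activity is structured by the
local prevalence of self-guided choice-sequence strategies.

## The problem

In a self-guided sequence task, a rat chooses between a left and a right
nose port on every trial (with a mandatory center-port entry in between) and
is rewarded only when its recent choices complete a latent target sequence
such as `RRL`. The target changes without warning every few hundred trials,
so the animal alternates between exploiting a discovered sequence —
concatenating it dozens of times — and transiently exploring alternatives.
Each sequence is therefore executed in different *global contexts* (as the
locally dominant strategy, or as an exploratory probe while another sequence
dominates) and under constantly varying *local context*, summarized by the
sequence's **prevalence**: the completions of that sequence in recent
history weighted by a causal half-Gaussian kernel (SD 20 trials),

```
prevalence_t = Σ_τ g(τ) · b_{t−τ},   g(τ) ∝ exp(−τ²/2σ²),  τ ≥ 0,
```

where `b` is 1 on the final trial of each completion. The package asks, on
spike trains recorded (or here, simulated) during sequence execution:

- Is the ensemble representation of a sequence reorganized between dominant
  and exploratory contexts? (state-space centroid distance vs a
  label-shuffle null; per-unit transition scores)
- Do single neurons track sequence prevalence, beyond reward prevalence and
  movement covariates? (cross-validated explained variance,
  `EV = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` on held-out folds, negatives clamped to 0)
- Can prevalence be decoded from the population, even by a temporally fixed
  readout? (per-window decoders vs a shared-weight decoder,
  `prev_t = bias + Σ_i w_i · spikes_{i,k,t}` with one weight per neuron
  across all five analysis windows)

Activity is analyzed in five 500 ms windows anchored on port entries (side
entry of step 1; center and side entries of steps 2 and 3), as square roots
of spike counts for state-space work and as rates/counts for classifiers and
decoders. A bundled generator produces behavior, port-event timing, and
Poisson spike trains with known ground truth, so every stage is testable
without any data download.

## Worked example

```python
import numpy as np
from seqprev import parsing, statespace
from seqprev.synthetic import AgentConfig, NeuronConfig, TimingParams, simulate_session

bundle, truth = simulate_session(
    AgentConfig(n_trials=900, block_length_range=(250, 400), seed=1),
    TimingParams(seed=2),
    NeuronConfig(n_units=20, seed=3),
)
instances = [
    i for i in parsing.parse_session(bundle.trials)
    if i.seq == "RRL" and i.context in ("DOMINANT", "DOMINANT_TAIL", "EXPLORATORY")
]
tensor = statespace.bin_instance_activity(bundle.spikes, instances, bundle.trials)
labels = np.where(tensor.meta["context"] == "EXPLORATORY", "EXPLORATORY", "DOMINANT")
state = statespace.build_state_space(tensor)
null, observed, pct = statespace.shuffle_null(state, labels, n_shuffles=1000, seed=0)
print(f"RRL instances: {len(instances)}")
print(f"context centroid distance: {observed:.3f}")
print(f"label-shuffle null: {null.mean():.3f} +/- {null.std():.3f} (percentile {pct:.3f})")
```

prints

```
RRL instances: 178
context centroid distance: 0.690
label-shuffle null: 0.287 +/- 0.028 (percentile 1.000)
```

The 178 parsed `RRL` instances (170 dominant, 8 exploratory) form two clouds
in the 100-dimensional state space (20 units × 5 windows) whose centroids
sit 0.690 apart (per-dimension RMS units) — far outside the 0.287 ± 0.028
distribution obtained when the context labels are shuffled, i.e. the
ensemble genuinely reorganizes between dominant and exploratory execution of
the same sequence.

A command-line interface mirrors the library:
`seqprev simulate | parse | prevalence | statespace | decode-context |
encode | decode-prevalence | run-all | report`, each taking `--config`
(YAML), `--seed` and `--out`. `run-all` executes the full pipeline over
session directories (plain TSV tables) and writes per-stage tables plus a
summary keyed by a config hash; outputs are byte-identical across reruns
with the same config.

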
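# ovrnn — online value-RNN with random feedback

`ovrnn` simulates online temporal-difference (TD) learning of *state
representation* and *state value* in a recurrent rate network, for
computational-neuroscience work on how the cortico–basal-ganglia–dopamine
circuit could learn both at once without backpropagation.  A cortical RNN
`x(t+1) = f(A x(t) + B o(t))` feeds a striatal value readout
`v(t) = wᵀx(t)`; a scalar dopamine-like TD reward-prediction error

    δ(t) = r(t) + γ v(t+1) − v(t)

updates the readout (`w_j ← w_j + a_value δ x_j`) and the recurrent and
feed-forward connections
(`A_ij ← A_ij + a_RNN δ x_j(t−1) φ(x_i(t)) fb_i`, likewise `B`).  The
per-unit feedback `fb` is either the transported readout weight (`w`,
backprop-type) or a fixed random vector (`c`, feedback alignment), and
biologically constrained variants force activities, readout and feedback
non-negative — which keeps `w` and `c` within 90° of each other ("loose
alignment") from the start.  The package includes the Pavlovian and
probabilistic-timing conditioning tasks, two-alternative choice tasks with
an actor-critic extension, an excitatory/inhibitory (Dale's law) variant,
exact and Monte-Carlo true-value oracles, and the alignment, value-error
and dimensionality analyses.  See `docs/methods.md` for the model details
and conventions.

## Worked example

Train 20 independent 7-unit networks with fixed random feedback on the
Pavlovian task (cue, reward 3 steps later, inter-trial interval 4–7 steps)
and relate feedback alignment to learning:

```python
import numpy as np
from scipy import stats
from ovrnn import TaskSpec, dp_true_values
from ovrnn.runner import run_population

spec = TaskSpec(kind="pavlovian", delay=3)
table = dp_true_values(spec, gamma=0.8)
print("oracle values (cue..reward):",
      {s: float(round(table.values[s], 3)) for s in range(0, 4)})

pop = run_population("oVRNNrf", 7, spec, n_trials=1000, n_sims=20,
                     master_seed=1, record_angle=True, probe_trials=[1000])
ang = pop.angles_at(1000)
val = pop.pre_reward_values(1000)
r, p = stats.pearsonr(ang, val)
print(f"mean w-c angle at trial 1000: {ang.mean():.1f} deg")
print(f"angle-value correlation over 20 runs: r={r:.3f} (p={p:.3f})")
print(f"mean squared value-error at trial 1000: "
      f"{pop.msve_at(1000, table).mean():.4f}")
```

prints

```
oracle values (cue..reward): {0: 0.523, 1: 0.757, 2: 0.946, 3: 0.183}
mean w-c angle at trial 1000: 46.1 deg
angle-value correlation over 20 runs: r=-0.438 (p=0.054)
mean squared value-error at trial 1000: 0.0884
```

The oracle values are the expected discounted returns of the four states
from the cue timing to the reward timing.  The mean `w`–`c` angle has
fallen from near 90° (chance for random vectors) to 46°: the value weights
aligned to the fixed random feedback during learning.  The negative
correlation says that runs whose weights aligned better also developed a
larger pre-reward value — the feedback-alignment mechanism at work.  The
value error is the mean squared difference between learned and oracle
values over those states, on the scale of the TD fixed point.

A thin CLI wraps the same machinery
(`ovrnn simulate|sweep|true-values|analyze|fixtures`), e.g.

```
ovrnn true-values --task prob-task1
ovrnn simulate --variant oVRNNrf-bio --n-units 12 --trials 1500 --sims 100 --out results/
```

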
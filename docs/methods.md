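# Methods

## Model

The package simulates online temporal-difference (TD) learning of a state
representation and a state value in a recurrent rate network, in the
standard cortico–basal-ganglia mapping: a cortical RNN receives
observations and maintains activity `x`, a striatal readout estimates the
state value, and a dopamine-like scalar TD reward-prediction error
(TD-RPE) trains everything.

Dynamics and learning, per time step (one step ≈ 500 ms of real time, the
scale of slow cortical synaptic dynamics):

```
x(t+1) = f(A x(t) + B o(t))                     (recurrent state update)
v(t)   = wᵀ x(t)                                (value readout)
δ(t)   = r(t) + γ v(t+1) − v(t)                 (TD-RPE)
w_j    ← w_j + a_value δ(t) x_j(t)              (readout plasticity)
A_ij   ← A_ij + a_RNN δ(t) x_j(t−1) φ(x_i(t)) fb_i
B_ik   ← B_ik + a_RNN δ(t) o_k(t−1) φ(x_i(t)) fb_i
```

The connection update is the gradient of the squared value error with the
true error approximated by the TD-RPE and the recurrent influence
truncated to one step (an online rule: no backward pass through time).
The per-unit feedback weight `fb_i` is the crux:

| variant        | f (activation)        | φ (post-syn. factor)     | fb    | sign constraints |
|----------------|-----------------------|--------------------------|-------|------------------|
| oVRNNbp        | centered sigmoid      | (0.5+x)(0.5−x)           | w     | none             |
| oVRNNrf        | centered sigmoid      | (0.5+x)(0.5−x)           | c ~ N(0,1)  | none       |
| oVRNNbp-rev    | positive sigmoid      | x(1−x)                   | w     | w ≥ 0, x ∈ (0,1) |
| oVRNNrf-bio    | positive sigmoid      | x(1−x) for x≤½, else ¼   | c ~ U(0,1)  | w, c ≥ 0   |
| oVRNNrf-rev    | positive sigmoid      | x(1−x)                   | c ~ U(0,1)  | w, c ≥ 0   |

`fb = w` is the backprop-type rule (the readout weights are "transported"
to the recurrent synapses); `fb = c` replaces them with a fixed random
vector — feedback alignment (FA).  Uniform-feedback controls set
`c = s·(1,…,1)` with a random or fixed coefficient.  Untrained controls
freeze `A, B` at initialization (naive) or at an element-wise permutation
of the matrices learned by a matched trained run (shuffled); their readout
still learns.  The monotone-saturating φ is the biologically motivated
replacement of the sigmoid derivative: plasticity grows with postsynaptic
activity and saturates, instead of vanishing for strongly active units.

Defaults (all overridable per `AgentConfig`): γ = 0.8; a_RNN = 0.1;
a_value = 0.1/(n/7) for the centered family and 0.1/(n/12) for the
constrained family, so total readout plasticity is comparable across
network sizes n; a halved scheme multiplies both by 0.5.  A, B and
(centered) x initialize from standard normal draws; constrained x from
U(0,1); w from 0.  Optional per-step decay w ← (1−dr)·w with dr = 0.001
or 0.002 counteracts the dominance of a few large w elements.

### Intra-step ordering

The paper family leaves the within-step order of updates open; we fix it
as: forward pass → TD-RPE from the *pre-update* readout → readout update
→ connection update with the same δ(t) → optional decay.  For the
backprop-type variants the connection update reads the **pre-update** w.
Using the post-update w instead injects a term
`a_RNN·a_value·δ²·x_i(t)·x_j(t−1)·φ_i` into the connection update —
Hebbian drift whose sign never follows the TD-RPE — and in our simulations
it destroys the probabilistic-timing discrimination of oVRNNbp-rev and
roughly doubles its value error.  The alternative remains available as
`AgentConfig(fb_post_update=True)` for sensitivity checks.  The very first
step of a run skips the connection update (no presynaptic activity
exists), and the E/I network's initial inhibitory activity is computed
with a zero observation.

## Tasks

All tasks run continuously (trials concatenated without gaps), which is
the ecologically motivated and harder setting: the network must treat cue
presentations as the same state although its activity differs across
trials.  Observation layout: (cue, reward[, distractor][, action1,
action2]); the reward element carries the reward size.  If an observation
arrives at step t, step t+1 is its "timing": the first step whose activity
reflects it.

* **Pavlovian**: cue observation at trial time 1, reward (size 1) at time
  1+delay (delay 3–6), trial end uniform on {4+delay, …, 7+delay}; hence
  the reward→cue interval (ITI) is uniform on {4,…,7}.
* **Probabilistic timing, task 1**: reward at time 3 or 5 with equal
  probability, every trial; **task 2**: 30%/30% early/late and 40%
  omitted.  Trial end stays at {7,…,10}.
* **Distractor**: an extra observation element is 1 with probability p
  (0–0.3) independently at every step.
* **Choice tasks**: cue at time 1, soft-max selection at time 2 between
  action 1 (size-2 reward at time 4) and action 2 (size-1 reward at time 4,
  or time 3 in the inter-temporal variant); the chosen action's observation
  unit is 1 at the selection step only.

## True-value oracles

Two independent routes compute the asymptotic ("true") value of every
labelled state.  The Monte-Carlo route replays the published recipe:
simulate sequences of trials with the first inter-trial gap pinned,
average cumulative discounted rewards counted from one step after the
start state (a reward one step ahead contributes γ¹), then average the
gap-specific tables; states at and before the cue average only over the
gaps the agent still considers possible (the agent is not assumed to track
elapsed ITI time).  Defaults are 1000 sequences × 1000 trials (Pavlovian)
and 10000 sequences (probabilistic tasks); the test suite scales these to
250 × 100, which the propagated standard errors account for.  The
dynamic-programming route solves the renewal equations in closed form —
for example the cue value obeys v = γᵈ(1 + E[γ^ITI]·v) — with belief
states for the probabilistic tasks.  The two routes agree within three
Monte-Carlo standard errors on every state; the pre-cue standard errors
are computed from per-sequence linear combinations because the offsets
within one gap condition share sequences.

Beliefs collapse at an observation's timing (one step after the
observation), consistent with the network's own lag: in task 1 the state
after no early reward predicts the late reward with certainty, so the
expected TD-RPE at the late reward is exactly 0; in task 2 the same state
leaves probability 3/7 on "late", so the late reward's TD-RPE is
1 − 3/7 = 4/7 and exceeds the early reward's 0.7 − 0.3γ² ≈ 0.508.

Two value conventions coexist and are kept explicit.  The "+1-start"
count V equals γ times the standard TD fixed point; tables store V (what
the published procedure estimates), expected TD-RPEs are formed from V/γ
(so fully predicted rewards give δ = 0), and the mean squared value-error
(MSVE) compares learned values against V/γ — the value the TD rule itself
converges to.  Comparing against V instead systematically flatters
untrained controls (a ~20% scale mismatch) and we found it reverses the
trained-vs-untrained ordering at intermediate network sizes.  The raw
convention is available behind `expected_td_rpe(..., convention="raw")`.

## E/I and actor-critic extensions

The Dale's-law variant splits the RNN into n excitatory units (positive
sigmoid) and n paired linear inhibitory units: excitation takes one step,
the paired I→E inhibition (strength h = 1) acts within the step, so the
forward pass equals a plain RNN with effective weights (A_E − h·A_I,
B_E − h·B_I) — an exact identity the tests check at machine precision.
Weights initialize as max(0, 3+z); only connections onto E-units learn.

The actor-critic adds two non-negative preference rows U (action values
q = U·x), soft-max choice with inverse temperature β ∈ {1, 2} at the step
after the cue, preference updates u_kj ← u_kj + a_pref δ(t) x_j(t) for the
selected row, and a per-step decay (1−0.001) on all preferences.  The
update schedule applies from the selection step to trial end by default —
letting the reward's TD-RPE reach the preference through the
action-conditioned activity — with a selection-step-only alternative
(`update_schedule="selection-only"`).

## Analyses

MSVE: mean squared difference between learned and oracle values over the
states from cue timing to reward timing inclusive (delay+1 states).
Alignment: the angle between w and c, recorded at the end of every trial
(undefined at w = 0, so series start at trial 2); two non-negative vectors
are never more than 90° apart ("loose alignment"), which is the chance
level of the unconstrained case.  Dimensionality: eigenvalue shares of the
covariance of the activity time series (raw ratios are exported; any log
is presentation).  Statistics follow the conventional forms: SEM = SD/√N,
Cohen's d with the average-variance denominator, Pearson correlation.
The FA mechanism diagnostics replay a forward pass with updated
connections to obtain the hypothetical activity change, whose angle to c
(signed by the TD-RPE) stays below 90°, and multiply TD-RPEs of successive
trials at the same state to show sign persistence.

## Reproducibility and problem sizes

A master seed spawns one substream per simulation via
`numpy.random.SeedSequence`, so populations are bit-reproducible and
extending a population never changes existing runs; shuffled controls
derive their source runs from a disjoint substream.  The package's study
conditions are those of the source experiments: 100 simulations per
condition; 1000 trials (7-unit centered family), 1500 trials (12-unit
constrained family), 2000 trials for the probabilistic tasks (20 units),
3000 trials for the choice tasks.  The test suite runs these sizes
directly; the oracle cross-checks use the scaled-down Monte-Carlo sizes
stated above.  What passing shows is internal consistency of this model
family on its synthetic tasks — the generator emulates the published task
statistics exactly, but no feature of real neural data (noise,
non-stationarity, heterogeneous time constants) is represented.

## Known limitations

* The online rule truncates credit assignment to one step; long
  cue–reward delays degrade accuracy, as in the source experiments.
* The probabilistic-timing discrimination (task-1 early > late) is a
  small effect at these problem sizes: present in the mean over 100
  simulations but not individually significant for every variant.
* Choice behavior is soft-max; no attractor-based selection dynamics, no
  D1/D2 pathway separation, no spiking or dendritic mechanisms.
* Exact reproduction of the original pseudo-random streams is out of
  scope; stochastic quantities reproduce within sampling error only.
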
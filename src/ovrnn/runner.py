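"""Experiment execution: seeding, simulation loops, and population sweeps.

A master seed spawns one independent substream per simulation through
``numpy.random.SeedSequence``, so runs are exactly reproducible and adding
simulations never perturbs earlier ones.  The drivers return in-memory
result objects; ``run_experiment`` adds the file-output layer (metric CSVs
plus a JSON manifest echoing every convention flag).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .actor import ActorCriticAgent, run_choice_task
from .analysis import msve, vector_angle
from .core import VARIANTS, AgentConfig, ValueRNNAgent
from .ei import EI_VARIANTS, EIAgent, EIConfig
from .tasks import TaskSpec, conditioning_stream, with_distractor
from .true_values import dp_true_values

__all__ = ["SimResult", "PopulationResult", "ExperimentConfig",
           "make_agent", "run_simulation", "run_population",
           "run_choice_population", "run_experiment", "sim_rngs"]


def sim_rngs(master_seed: int, n_sims: int, *, key: int = 0,
             ) -> list[tuple[np.random.Generator, np.random.Generator]]:
    """Per-simulation (task, agent) generator pairs from one master seed."""
    children = np.random.SeedSequence([master_seed, key]).spawn(n_sims)
    out = []
    for ss in children:
        task_ss, agent_ss = ss.spawn(2)
        out.append((np.random.default_rng(task_ss),
                    np.random.default_rng(agent_ss)))
    return out


def make_agent(variant: str, n: int, m: int, rng: np.random.Generator,
               source=None, lr_scale: float = 1.0, w_decay: float = 0.0,
               gamma: float = 0.8):
    """Instantiate a core or E/I agent by variant name."""
    if variant in EI_VARIANTS:
        return EIAgent(EIConfig(variant=variant, n=n, gamma=gamma,
                                lr_scale=lr_scale, w_decay=w_decay),
                       m, rng=rng, source=source)
    cfg = AgentConfig(variant=variant, n=n, gamma=gamma, lr_scale=lr_scale,
                      w_decay=w_decay)
    return ValueRNNAgent(cfg, m, rng=rng, source=source)


@dataclass
class SimResult:
    """Per-simulation metric series and probe records."""

    angles: Optional[np.ndarray] = None          # (n_trials,) w-c angle, deg
    probe_values: dict = field(default_factory=dict)   # trial -> {rel: v}
    probe_deltas: dict = field(default_factory=dict)   # trial -> {rel: delta}
    reward_delta: Optional[np.ndarray] = None    # (n_trials,) TD-RPE at reward
    trial_type: Optional[np.ndarray] = None
    activity: Optional[np.ndarray] = None        # (T, n) when recorded
    final_w: Optional[np.ndarray] = None
    final_c: Optional[np.ndarray] = None
    final_matrices: Optional[tuple] = None       # source for shuffled controls

    def pre_reward_value(self, probe_trial: int, delay: int = 3) -> float:
        return self.probe_values[probe_trial][delay - 1]

    def learned_values(self, probe_trial: int) -> dict:
        return self.probe_values[probe_trial]


def run_simulation(agent, stream, *, probe_trials: Sequence[int] = (),
                   record_angle: bool = False,
                   record_activity: bool = False) -> SimResult:
    """Drive one agent through a generated stream, logging metrics.

    The w-c angle is recorded at the end of every trial; probe values and
    TD-RPEs are the per-step records of the requested (1-based) trials,
    keyed by the step's timing from the cue; ``reward_delta`` holds each
    trial's TD-RPE at the reward-observation step.
    """
    probe = set(int(p) for p in probe_trials)
    n_trials = stream.n_trials
    angles = np.full(n_trials, np.nan) if record_angle else None
    reward_delta = np.full(n_trials, np.nan)
    res = SimResult(angles=angles, reward_delta=reward_delta,
                    trial_type=stream.trial_type.copy())
    acts = [] if record_activity else None
    obs, rew = stream.obs, stream.r
    trial, rel = stream.trial, stream.rel_cue
    last_step_of_trial = np.zeros(n_trials, dtype=int)
    last_step_of_trial[:] = stream.trial_start + stream.trial_len - 1
    c = getattr(agent, "c", None)
    for t in range(stream.n_steps):
        if acts is not None:
            acts.append(agent.x.copy() if hasattr(agent, "x")
                        else agent.state.x_E.copy())
        out = agent.step(obs[t], float(rew[t]))
        k = int(trial[t])
        if rew[t] > 0:
            reward_delta[k] = out.delta
        if (k + 1) in probe:
            res.probe_values.setdefault(k + 1, {})[int(rel[t])] = out.v
            res.probe_deltas.setdefault(k + 1, {})[int(rel[t])] = out.delta
        if record_angle and c is not None and t == last_step_of_trial[k]:
            angles[k] = vector_angle(agent.w, c)
    if acts is not None:
        res.activity = np.asarray(acts)
    res.final_w = agent.w.copy()
    res.final_c = None if c is None else c.copy()
    st = agent.state
    if hasattr(st, "A_E"):
        res.final_matrices = (st.A_E.copy(), st.A_I.copy(),
                              st.B_E.copy(), st.B_I.copy())
    else:
        res.final_matrices = (st.A.copy(), st.B.copy())
    return res


@dataclass
class PopulationResult:
    """Stacked per-simulation results of one (variant, n, task) condition."""

    variant: str
    n: int
    sims: list[SimResult]

    @property
    def n_sims(self) -> int:
        return len(self.sims)

    def angle_matrix(self) -> np.ndarray:
        return np.vstack([s.angles for s in self.sims])

    def pre_reward_values(self, probe_trial: int, delay: int = 3,
                          ) -> np.ndarray:
        return np.array([s.pre_reward_value(probe_trial, delay)
                         for s in self.sims])

    def angles_at(self, trial: int) -> np.ndarray:
        return np.array([s.angles[trial - 1] for s in self.sims])

    def msve_at(self, probe_trial: int, true_table) -> np.ndarray:
        """Per-simulation MSVE over the cue..reward states at a probe trial.

        Learned values are compared with the oracle values on the agent's
        own scale (the TD fixed point, stored value / gamma)."""
        d = true_table.delay
        tv = {s: true_table.std_value(s) for s in range(0, d + 1)}
        out = []
        for s in self.sims:
            out.append(msve(s.learned_values(probe_trial), tv, range(0, d + 1)))
        return np.array(out)

    def reward_deltas_by_type(self, within: int, type_code: int,
                              ) -> np.ndarray:
        """Per-sim TD-RPE at reward in the latest trial of the given type
        within the first ``within`` trials."""
        out = np.full(self.n_sims, np.nan)
        for i, s in enumerate(self.sims):
            ok = np.nonzero((s.trial_type[:within] == type_code)
                            & ~np.isnan(s.reward_delta[:within]))[0]
            if ok.size:
                out[i] = s.reward_delta[ok[-1]]
        return out


def _source_matrix_key(variant: str) -> Optional[str]:
    if variant == "untrained-shuffled-bio":
        return "oVRNNrf-bio"
    if variant == "untrained-shuffled-ei":
        return "oVRNNrf-bio-ei"
    return None


def run_population(variant: str, n: int, spec: TaskSpec, n_trials: int,
                   n_sims: int, master_seed: int, *,
                   probe_trials: Sequence[int] = (),
                   record_angle: bool = False,
                   record_activity: bool = False,
                   lr_scale: float = 1.0, w_decay: float = 0.0,
                   gamma: float = 0.8) -> PopulationResult:
    """Run ``n_sims`` independent simulations of one conditioning condition.

    Shuffled-untrained controls first run the matched trained source model
    on its own seeds and permute the learned connection matrices.
    """
    needs = (variant in VARIANTS and VARIANTS[variant].get("needs_source")) \
        or (variant in EI_VARIANTS
            and EI_VARIANTS[variant].get("needs_source"))
    sources = [None] * n_sims
    if needs:
        src_variant = _source_matrix_key(variant)
        src = _run_population_inner(src_variant, n, spec, n_trials, n_sims,
                                    master_seed, [None] * n_sims, (), False,
                                    False, lr_scale, 0.0, gamma,
                                    key_offset=999)
        sources = [s.final_matrices for s in src.sims]
    return _run_population_inner(variant, n, spec, n_trials, n_sims,
                                 master_seed, sources, probe_trials,
                                 record_angle, record_activity, lr_scale,
                                 w_decay, gamma, key_offset=0)


def _run_population_inner(variant, n, spec, n_trials, n_sims, master_seed,
                          sources, probe_trials, record_angle,
                          record_activity, lr_scale, w_decay, gamma,
                          key_offset):
    spec = dataclasses.replace(spec, n_trials=n_trials)
    sims = []
    for i, (task_rng, agent_rng) in enumerate(
            sim_rngs(master_seed, n_sims, key=key_offset)):
        stream = conditioning_stream(spec, task_rng)
        if spec.distractor_p > 0:
            stream = with_distractor(stream, spec.distractor_p, task_rng)
        m = stream.obs.shape[1]
        agent = make_agent(variant, n, m, agent_rng, source=sources[i],
                           lr_scale=lr_scale, w_decay=w_decay, gamma=gamma)
        sims.append(run_simulation(agent, stream, probe_trials=probe_trials,
                                   record_angle=record_angle,
                                   record_activity=record_activity))
    return PopulationResult(variant=variant, n=n, sims=sims)


def run_choice_population(variant: str, n: int, kind: str, n_trials: int,
                          n_sims: int, master_seed: int, *, beta: float = 2.0,
                          update_schedule: str = "to-trial-end",
                          lr_scale: float = 1.0) -> list:
    """Closed-loop choice-task runs; returns one ChoiceLog per simulation.

    For shuffled controls the source matrices come from matched trained
    closed-loop runs on their own seed substreams.
    """
    needs = variant in VARIANTS and VARIANTS[variant].get("needs_source")
    sources = [None] * n_sims
    if needs:
        pairs = _run_choice_inner("oVRNNrf-bio", n, kind, n_trials, n_sims,
                                  master_seed, beta, update_schedule,
                                  lr_scale, [None] * n_sims,
                                  return_agents=True, key_offset=999)
        sources = [(a.critic.state.A.copy(), a.critic.state.B.copy())
                   for _, a in pairs]
    return _run_choice_inner(variant, n, kind, n_trials, n_sims, master_seed,
                             beta, update_schedule, lr_scale, sources,
                             return_agents=False, key_offset=0)


def _run_choice_inner(variant, n, kind, n_trials, n_sims, master_seed, beta,
                      update_schedule, lr_scale, sources, return_agents,
                      key_offset):
    spec = TaskSpec(kind=kind, n_trials=n_trials)
    logs = []
    for i, (task_rng, agent_rng) in enumerate(
            sim_rngs(master_seed, n_sims, key=key_offset)):
        cfg = AgentConfig(variant=variant, n=n, lr_scale=lr_scale)
        agent = ActorCriticAgent(cfg, m=4, beta=beta,
                                 update_schedule=update_schedule,
                                 rng=agent_rng, source=sources[i])
        log = run_choice_task(agent, spec, n_trials, task_rng)
        logs.append((log, agent) if return_agents else log)
    return logs


# ---------------------------------------------------------------------------
# configuration-driven execution with file output
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """One runnable experiment: agent variant(s) x network sizes x task."""

    variants: list[str]
    n_units: list[int]
    task: str = "pavlovian"
    delay: int = 3
    distractor_p: float = 0.0
    n_trials: int = 1000
    n_sims: int = 100
    probe_trials: list[int] = field(default_factory=list)
    lr_scale: float = 1.0
    w_decay: float = 0.0
    gamma: float = 0.8
    master_seed: int = 1
    out_dir: str = "results"

    def __post_init__(self):
        choice = {"choice-1", "choice-2"}
        for v in self.variants:
            known = v in VARIANTS or v in EI_VARIANTS
            if not known:
                raise ValueError(f"unknown variant {v!r}")
            if self.task in choice:
                raise ValueError(
                    "choice tasks need the actor-critic runner "
                    "(run_choice_population), not run_experiment")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the configured sweep; write metric CSVs and a manifest."""
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = TaskSpec(kind=config.task, delay=config.delay,
                    distractor_p=config.distractor_p,
                    n_trials=config.n_trials)
    probe = list(config.probe_trials) or [config.n_trials]
    table = dp_true_values(spec, gamma=config.gamma) \
        if config.task == "pavlovian" else None
    rows = []
    for variant in config.variants:
        for n in config.n_units:
            pop = run_population(variant, n, spec, config.n_trials,
                                 config.n_sims, config.master_seed,
                                 probe_trials=probe, record_angle=True,
                                 lr_scale=config.lr_scale,
                                 w_decay=config.w_decay, gamma=config.gamma)
            for i, s in enumerate(pop.sims):
                row = dict(variant=variant, n=n, sim=i)
                if table is not None:
                    row["msve"] = pop.msve_at(probe[-1], table)[i]
                    row["pre_reward_value"] = s.pre_reward_value(
                        probe[-1], config.delay)
                if s.angles is not None and not np.all(np.isnan(s.angles)):
                    row["angle_final"] = s.angles[probe[-1] - 1]
                rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "metrics.csv", index=False, float_format="%.17g")
    summary = (df.drop(columns=["sim"]).groupby(["variant", "n"])
               .agg(["mean", "sem"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    summary.reset_index().to_csv(out / "summary.csv", index=False,
                                 float_format="%.17g")
    manifest = dataclasses.asdict(config)
    manifest.update(
        version=__version__,
        conventions=dict(
            step_order="value-readout update before connection update, "
                       "same TD-RPE; TD-RPE uses pre-update readout",
            w_decay_position="after the TD update within a step",
            reward_alignment="reward scalar at the observation-carrying step",
            msve_states="cue timing .. reward timing inclusive",
            value_count="rewards counted from +1; TD-RPE from V/gamma",
        ))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
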
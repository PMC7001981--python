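"""Batch simulation harness and metric extraction.

Runs one of the four controllers (full deliberation or caching schemes 1-3)
for ``n_reps`` independent repetitions of an ``n_trials``-trial session and
collects tidy per-(repetition, trial) records: reward, end-of-trial context
posterior and its normalised entropy, habitisation flags per choice point,
the maximum expected cached policy probability, the executed policy, and
deliberation-cost counters. Aggregation to per-trial means reproduces the
quantities plotted in the source figures (performance/uncertainty curves,
habitisation fractions, best-policy probability, cost).

Each repetition draws its random stream from a spawned seed sequence keyed
by (seed, rep), so changing ``n_reps`` never perturbs earlier repetitions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .caching import PolicyCache, run_trial_scheme1, run_trial_scheme2, run_trial_scheme3
from .inference import context_marginal, run_trial_full
from .model import GenerativeModel, build_model
from .world import CONTEXTS, N_CONTEXTS, TRIAL_LENGTH, context_at_trial

SCHEMES = ("full", "scheme1", "scheme2", "scheme3")


@dataclass
class ExperimentConfig:
    """Parameters of one batch experiment (defaults = study conditions)."""

    scheme: str = "scheme1"
    n_trials: int = 40
    n_reps: int = 100
    switch_trial: Optional[int] = 21  # context A -> D; None disables the switch
    schedule: Optional[List[Tuple[int, str]]] = None  # overrides switch_trial
    p_reward: float = 0.95
    p_reward_model: Optional[float] = None  # defaults to p_reward
    stability: float = 0.99
    p_th: float = 0.90
    gamma: float = 3.0
    utility: float = 1.3
    eta: float = 0.85
    seed: int = 0
    collect_snapshots: bool = False
    snapshot_states: Tuple[int, ...] = tuple(range(1, 41))

    def resolved_schedule(self) -> List[Tuple[int, str]]:
        if self.schedule is not None:
            return [(int(t), str(c)) for t, c in self.schedule]
        if self.switch_trial is None:
            return [(1, "A")]
        return [(1, "A"), (int(self.switch_trial), "D")]

    def validate(self) -> None:
        problems = []
        if self.scheme not in SCHEMES:
            problems.append(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.n_trials < 1:
            problems.append(f"n_trials must be >= 1, got {self.n_trials}")
        if self.n_reps < 1:
            problems.append(f"n_reps must be >= 1, got {self.n_reps}")
        for name in ("p_reward", "stability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if self.p_reward_model is not None and not 0.0 <= self.p_reward_model <= 1.0:
            problems.append(f"p_reward_model must be in [0, 1], got {self.p_reward_model}")
        if self.gamma <= 0:
            problems.append(f"gamma must be > 0, got {self.gamma}")
        if self.utility < 0:
            problems.append(f"utility must be >= 0, got {self.utility}")
        if not 0.0 < self.eta <= 1.0:
            problems.append(f"eta must be in (0, 1], got {self.eta}")
        try:
            sched = self.resolved_schedule()
            context_at_trial(1, sched)
        except ValueError as exc:
            problems.append(str(exc))
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    def build_model(self) -> GenerativeModel:
        p_model = self.p_reward if self.p_reward_model is None else self.p_reward_model
        return build_model(
            gamma=self.gamma,
            utility=self.utility,
            p_reward_model=p_model,
            stability=self.stability,
        )


@dataclass
class RunMetrics:
    """Raw per-(rep, trial) records plus optional cache snapshots."""

    config: ExperimentConfig
    trials: pd.DataFrame
    snapshots: Optional[pd.DataFrame] = None


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def run_experiment(config: ExperimentConfig) -> RunMetrics:
    """Run the configured scheme for all repetitions and collect metrics."""
    config.validate()
    model = config.build_model()
    schedule = config.resolved_schedule()
    ln4 = np.log(N_CONTEXTS)

    rows = []
    snap_rows = [] if config.collect_snapshots else None

    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        cache = PolicyCache.uniform(
            n_policies=model.n_policies, eta=config.eta, p_th=config.p_th
        )
        prev_ctx = np.full(N_CONTEXTS, 1.0 / N_CONTEXTS)
        prev_final_belief = None

        for trial in range(1, config.n_trials + 1):
            true_ctx = context_at_trial(trial, schedule)
            if config.scheme == "full":
                record = run_trial_full(
                    model, prev_ctx, true_ctx, config.p_reward, rng
                )
            elif config.scheme == "scheme1":
                record = run_trial_scheme1(
                    model, cache, prev_final_belief, prev_ctx, true_ctx,
                    config.p_reward, rng,
                )
            elif config.scheme == "scheme2":
                record = run_trial_scheme2(
                    model, cache, prev_ctx, true_ctx, config.p_reward, rng
                )
            else:
                record = run_trial_scheme3(
                    model, cache, prev_ctx, true_ctx, config.p_reward, rng
                )

            ctx_post = context_marginal(record.final_belief)
            with np.errstate(divide="ignore", invalid="ignore"):
                ent = -np.sum(np.where(ctx_post > 0, ctx_post * np.log(ctx_post), 0.0))
            row = {
                "rep": rep,
                "trial": trial,
                "true_context": true_ctx,
                "rewarded": record.rewarded,
                "habitised_at": np.nan if record.habitised_at is None else record.habitised_at,
                "executed_policy_id": record.executed_policy_id,
                "max_expected_policy_prob": record.max_expected_policy_prob,
                "context_entropy": float(ent / ln4),
                "n_efe_evals": record.n_efe_evals,
                "n_efe_terms": record.n_efe_terms,
            }
            for cp in range(TRIAL_LENGTH):
                row[f"habit_cp{cp + 1}"] = record.habit_flags[cp]
            for i, c in enumerate(CONTEXTS):
                row[f"p_ctx_{c}"] = float(ctx_post[i])
            rows.append(row)

            if snap_rows is not None:
                for s in config.snapshot_states:
                    col = cache.table[:, s - 1]
                    for pol_id in range(1, model.n_policies + 1):
                        snap_rows.append(
                            {
                                "rep": rep,
                                "trial": trial,
                                "state": s,
                                "policy": pol_id,
                                "probability": float(col[pol_id - 1]),
                            }
                        )

            prev_ctx = ctx_post
            prev_final_belief = record.final_belief

    trials = pd.DataFrame(rows)
    snapshots = pd.DataFrame(snap_rows) if snap_rows is not None else None
    return RunMetrics(config=config, trials=trials, snapshots=snapshots)


def summarize(metrics: RunMetrics) -> pd.DataFrame:
    """Per-trial aggregates (means over repetitions)."""
    df = metrics.trials
    agg = df.groupby("trial").agg(
        mean_reward=("rewarded", "mean"),
        mean_context_entropy=("context_entropy", "mean"),
        mean_max_expected_policy_prob=("max_expected_policy_prob", "mean"),
        mean_n_efe_evals=("n_efe_evals", "mean"),
        mean_n_efe_terms=("n_efe_terms", "mean"),
    )
    any_habit = df[[f"habit_cp{i}" for i in range(1, TRIAL_LENGTH + 1)]].any(axis=1)
    agg["frac_habitised"] = any_habit.groupby(df["trial"]).mean()
    for i in range(1, TRIAL_LENGTH + 1):
        agg[f"frac_habitised_cp{i}"] = df.groupby("trial")[f"habit_cp{i}"].mean()
    for c in CONTEXTS:
        agg[f"mean_p_ctx_{c}"] = df.groupby("trial")[f"p_ctx_{c}"].mean()
    return agg.reset_index()


def first_threshold_crossing(
    aggregate: pd.DataFrame,
    threshold: float,
    from_trial: int = 1,
    column: str = "mean_max_expected_policy_prob",
) -> Optional[int]:
    """Smallest trial >= from_trial whose aggregate value exceeds ``threshold``."""
    sub = aggregate[aggregate["trial"] >= from_trial]
    hits = sub[sub[column] > threshold]
    if hits.empty:
        return None
    return int(hits["trial"].iloc[0])


def policy_execution_fraction(metrics: RunMetrics, policy_id: int) -> pd.Series:
    """Per-trial fraction of repetitions that executed ``policy_id``."""
    df = metrics.trials
    return (df["executed_policy_id"] == policy_id).groupby(df["trial"]).mean()


def last_predominant_trial(
    metrics: RunMetrics,
    policy_id: int,
    from_trial: int = 1,
    min_fraction: float = 0.5,
) -> Optional[int]:
    """Last trial >= from_trial on which ``policy_id`` was executed by more
    than ``min_fraction`` of repetitions."""
    frac = policy_execution_fraction(metrics, policy_id)
    frac = frac[frac.index >= from_trial]
    hits = frac[frac > min_fraction]
    if hits.empty:
        return None
    return int(hits.index[-1])


def write_outputs(metrics: RunMetrics, outdir) -> None:
    """Write per-rep records, per-trial aggregates and a reproduction manifest."""
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    metrics.trials.to_csv(out / "trials.csv", index=False)
    summarize(metrics).to_csv(out / "aggregate.csv", index=False)
    if metrics.snapshots is not None:
        metrics.snapshots.to_csv(out / "cache_snapshots.csv", index=False)
    cfg = asdict(metrics.config)
    cfg["snapshot_states"] = list(cfg["snapshot_states"])
    manifest = {"config": cfg, "version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
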
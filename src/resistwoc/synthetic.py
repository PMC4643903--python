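"""Synthetic estimation experiments with the structure the method assumes.

The generator emulates the statistical shape of group estimation studies:

* first-round estimates are log-normal around the (possibly biased) center
  of each subject's subpopulation: ``x1 = exp(log truth + log_bias + eps)``
  with ``eps ~ N(0, log_sd)``;
* each subject carries a social weight drawn from their subpopulation
  (typically a mixture concentrated near 0 -- resisters -- and near 1 --
  conformists, the bimodal shape seen in real groups);
* the social signal is the geometric mean of first-round estimates under
  the full-information condition and the arithmetic mean under the
  aggregated condition;
* second-round estimates follow the weighted geometric-mean update rule,
  optionally with multiplicative log-normal update noise; the no-information
  control repeats the first estimate plus noise.

The deterministic update alone shrinks the pooled z-SD by (1 - ws); the
population-level prediction sqrt(1 - ws) additionally requires update noise
with SD ``sigma_p*sqrt(ws*(1-ws))`` (then Var(z2) = (1-ws)^2 + ws(1-ws) =
1-ws).  ``model_consistent_noise_sd`` computes that value so simulations can
match the population-level model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (Condition, ExperimentTable, InvalidInputError, SignalMode,
                   predict_update, social_signal)

__all__ = ["SubpopulationSpec", "SyntheticConfig",
           "model_consistent_noise_sd", "generate_experiment",
           "generate_study", "study_subpopulations",
           "biased_crowd_subpopulations", "DEFAULT_CONFIDENCE_PROBS"]

#: Declared-confidence distribution (independent of accuracy): most subjects
#: declare low confidence, as real groups do.
DEFAULT_CONFIDENCE_PROBS = (0.30, 0.25, 0.20, 0.12, 0.08, 0.05)


@dataclass(frozen=True)
class SubpopulationSpec:
    """One subpopulation of subjects.

    fraction : share of the crowd in this subpopulation.
    log_bias : offset of the subpopulation's log-estimate center from log
        truth (0 = unbiased).
    log_sd : SD of log estimates within the subpopulation.
    ws_center, ws_sd : Gaussian parameters of the subpopulation's social
        weight (ws_sd = 0 gives a common weight).
    """

    fraction: float
    log_bias: float = 0.0
    log_sd: float = 1.0
    ws_center: float = 0.0
    ws_sd: float = 0.0


def study_subpopulations(log_sd: float = 1.39) -> tuple[SubpopulationSpec, ...]:
    """Unbiased crowd with the bimodal social-weight structure of real
    groups: roughly equal numbers resisting (ws near 0) and conforming
    (ws near 1).  The default within-group log SD matches the mean
    pre-influence dispersion observed across real experiments (1.39)."""
    return (
        SubpopulationSpec(fraction=0.5, log_bias=0.0, log_sd=log_sd,
                          ws_center=0.05, ws_sd=0.05),
        SubpopulationSpec(fraction=0.5, log_bias=0.0, log_sd=log_sd,
                          ws_center=0.9, ws_sd=0.1),
    )


def biased_crowd_subpopulations(resist_fraction: float = 0.25,
                                conformist_bias: float = -1.0,
                                log_sd: float = 0.6) -> tuple[SubpopulationSpec, ...]:
    """Crowd where only a resistant minority is unbiased.

    A fraction of resisters (ws near 0) centered on the truth and a
    conformist majority (ws near 1) sharing a multiplicative bias
    ``exp(conformist_bias)``.  This is the regime where the plain crowd
    geometric mean is pulled off target but the resisting subgroup is not.
    ``log_sd`` is the *within*-subpopulation dispersion; real groups show
    within-cluster spreads around 0.5-0.65 in log units (e.g. clusters of
    512 +/- 269 and 216 +/- 157 on a border-length question), with the much
    larger pooled SD driven by the between-subgroup bias.
    """
    return (
        SubpopulationSpec(fraction=resist_fraction, log_bias=0.0,
                          log_sd=log_sd, ws_center=0.05, ws_sd=0.05),
        SubpopulationSpec(fraction=1.0 - resist_fraction,
                          log_bias=conformist_bias, log_sd=log_sd,
                          ws_center=0.9, ws_sd=0.1),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for one generated experiment."""

    n_subjects: int = 48
    truth: float = 100.0
    subpopulations: tuple[SubpopulationSpec, ...] = field(
        default_factory=study_subpopulations)
    condition: Condition = Condition.FULL
    update_noise_sd: float = 0.0
    seed: object = 0
    ws_clip: tuple[float, float] | None = None
    confidence_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidInputError("need at least 2 subjects")
        if self.truth <= 0:
            raise InvalidInputError("truth must be positive")
        total = sum(s.fraction for s in self.subpopulations)
        if not self.subpopulations or abs(total - 1.0) > 1e-9:
            raise InvalidInputError("subpopulation fractions must sum to 1")
        if self.update_noise_sd < 0:
            raise InvalidInputError("update_noise_sd must be >= 0")


def model_consistent_noise_sd(sigma_p: float, ws: float) -> float:
    """Log-domain update-noise SD under which the generated second round
    reproduces the population-level posterior N(., sigma_p*sqrt(1-ws))."""
    return float(sigma_p * np.sqrt(max(ws * (1.0 - ws), 0.0)))


def generate_experiment(config: SyntheticConfig,
                        group_id: str = "g1", question_id: str = "q1",
                        ) -> tuple[ExperimentTable, pd.DataFrame]:
    """Generate one two-round experiment.

    Returns the experiment table and a ground-truth frame with each
    subject's drawn social weight and subpopulation index.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    fracs = np.array([s.fraction for s in config.subpopulations])
    pop = rng.choice(len(fracs), size=n, p=fracs)
    bias = np.array([config.subpopulations[p].log_bias for p in pop])
    lsd = np.array([config.subpopulations[p].log_sd for p in pop])
    wc = np.array([config.subpopulations[p].ws_center for p in pop])
    wsd = np.array([config.subpopulations[p].ws_sd for p in pop])
    x1 = np.exp(np.log(config.truth) + bias + rng.normal(0.0, 1.0, n) * lsd)
    ws = wc + rng.normal(0.0, 1.0, n) * wsd
    if config.ws_clip is not None:
        ws = np.clip(ws, *config.ws_clip)
    noise = rng.normal(0.0, 1.0, n) * config.update_noise_sd
    condition = Condition(config.condition)
    if condition is Condition.NONE:
        x2 = x1 * np.exp(noise)
    else:
        mode = (SignalMode.GEOMETRIC if condition is Condition.FULL
                else SignalMode.ARITHMETIC)
        sig = social_signal(x1, mode)
        x2 = predict_update(x1, ws, sig) * np.exp(noise)
    subjects = [f"{group_id}-s{i + 1}" for i in range(n)]
    rows = {
        "subject_id": subjects * 2,
        "round": [1] * n + [2] * n,
        "estimate": np.concatenate([x1, x2]),
    }
    if config.confidence_probs is not None:
        probs = np.asarray(config.confidence_probs, dtype=float)
        if probs.size != 6 or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise InvalidInputError("confidence_probs must be 6 probabilities summing to 1")
        conf = rng.choice(np.arange(1, 7), size=n, p=probs)
        rows["confidence"] = np.concatenate([conf, conf])
    table = ExperimentTable(data=pd.DataFrame(rows), group_id=group_id,
                            question_id=question_id, condition=condition,
                            truth=config.truth)
    truth_ws = pd.DataFrame({"subject_id": subjects, "ws": ws,
                             "subpopulation": pop})
    return table, truth_ws


#: Default per-question condition layout: two questions per condition, as in
#: a 6-question study design.
DEFAULT_CONDITION_LAYOUT = (Condition.FULL, Condition.FULL,
                            Condition.AGGREGATED, Condition.AGGREGATED,
                            Condition.NONE, Condition.NONE)


def generate_study(n_groups: int = 12, n_subjects: int = 12,
                   n_questions: int = 6,
                   conditions: Sequence[Condition] = DEFAULT_CONDITION_LAYOUT,
                   template: SyntheticConfig | None = None,
                   seed: object = 0,
                   ) -> list[tuple[ExperimentTable, pd.DataFrame]]:
    """Factorial groups x questions study with per-cell derived seeds.

    Defaults mirror a study of 12 groups of 12 people answering 6 questions,
    two per information condition.  Each cell's seed is derived from the
    study seed and its (group, question) index, so the whole study is
    reproducible and cells are independent.
    """
    template = template or SyntheticConfig(n_subjects=n_subjects)
    out = []
    for g in range(n_groups):
        for q in range(n_questions):
            cell_seed = np.random.SeedSequence((seed, g, q))
            cfg = replace(template, n_subjects=n_subjects,
                          condition=conditions[q % len(conditions)],
                          seed=cell_seed)
            out.append(generate_experiment(cfg, group_id=f"g{g + 1}",
                                           question_id=f"q{q + 1}"))
    return out
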
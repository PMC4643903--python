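"""Log-domain model of numeric estimation under social influence.

People asked to estimate a positive quantity (a length, a count, a density)
produce first guesses that are approximately log-normal across a group.  After
seeing social information -- either every group member's estimate or just
their arithmetic mean -- each individual revises their guess.  The model here
is a weighted geometric mean of private and social information,

    x2 = x1**(1 - ws) * xs**ws,   equivalently   y2 = (1 - ws)*y1 + ws*mu_s

with ``y = log x``, ``xs`` the social signal shown to the subject,
``mu_s = log xs``, and ``ws`` the individual's *social weight*: the fraction
of the log-domain distance toward the signal that the individual moves.
``ws = 0`` means full resistance to social influence; ``ws = 1`` means full
adoption of the signal.  At the population level the log-estimate
distribution N(mu_p, sigma_p) before influence becomes

    N((1-ws)*mu_p + ws*mu_s,  sigma_p*sqrt(1-ws))

after influence; when the signal is the arithmetic mean of log-normal
estimates this shifts the mean upward by ``ws*sigma_p**2/2``.

This module implements the signals, the update rule, per-individual inference
of ``ws``, z-score pooling across experiments and the population-level
predictions.  Everything uses natural logarithms.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "SignalMode",
    "ResistWocError",
    "InvalidInputError",
    "InsufficientDataError",
    "DegenerateDataError",
    "EQ_TOL",
    "ExperimentTable",
    "PriorSummary",
    "SocialSignal",
    "SocialWeightRecord",
    "PosteriorPrediction",
    "PooledSample",
    "geometric_mean",
    "social_signal",
    "predict_update",
    "infer_social_weight",
    "social_weights",
    "prior_summary",
    "predict_posterior",
    "zscore_pool",
    "fit_social_weight_from_variance",
]

#: Identifiability tolerance for the social-weight denominator |mu_s - y1|.
EQ_TOL = 1e-8


class ResistWocError(Exception):
    """Base class for errors raised by this package."""


class InvalidInputError(ResistWocError):
    """Malformed or out-of-domain input (non-positive estimate, bad column...)."""


class InsufficientDataError(ResistWocError):
    """Too few observations to compute the requested quantity."""


class DegenerateDataError(ResistWocError):
    """Data whose dispersion or configuration makes the quantity undefined."""


class Condition(str, enum.Enum):
    """Information regime of an experiment."""

    FULL = "full"          # subjects see every group member's estimate
    AGGREGATED = "aggregated"  # subjects see only the arithmetic mean
    NONE = "none"          # control: second estimate without social input


class SignalMode(str, enum.Enum):
    GEOMETRIC = "geometric"
    ARITHMETIC = "arithmetic"


#: Signal shown to subjects under each information condition.
CONDITION_SIGNAL_MODE = {
    Condition.FULL: SignalMode.GEOMETRIC,
    Condition.AGGREGATED: SignalMode.ARITHMETIC,
}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExperimentTable:
    """One experiment: a group answering one question under one condition.

    ``data`` holds one row per (subject, round) with columns ``subject_id``,
    ``round`` (integer >= 1) and ``estimate`` (strictly positive), plus an
    optional ``confidence`` column with declared confidence in 1..6.
    """

    data: pd.DataFrame
    group_id: str = "g1"
    question_id: str = "q1"
    condition: Condition = Condition.FULL
    truth: float | None = None

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        required = {"subject_id", "round", "estimate"}
        missing = required - set(self.data.columns)
        if missing:
            raise InvalidInputError(f"missing columns: {sorted(missing)}")
        est = pd.to_numeric(self.data["estimate"], errors="coerce")
        if est.isna().any() or (est <= 0).any():
            raise InvalidInputError("estimates must be strictly positive numbers")
        if (pd.to_numeric(self.data["round"]) < 1).any():
            raise InvalidInputError("round indices must be >= 1")
        if self.data.duplicated(["subject_id", "round"]).any():
            raise InvalidInputError("duplicate (subject_id, round) rows")
        if self.truth is not None and self.truth <= 0:
            raise InvalidInputError("truth must be positive")

    @property
    def rounds(self) -> list[int]:
        return sorted(int(r) for r in self.data["round"].unique())

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def estimates(self, round: int = 1) -> pd.Series:
        """Estimates in one round, indexed by subject_id."""
        sub = self.data[self.data["round"] == round]
        if sub.empty:
            raise InsufficientDataError(f"no records for round {round}")
        return sub.set_index("subject_id")["estimate"].astype(float)

    def confidences(self) -> pd.Series:
        if "confidence" not in self.data.columns:
            raise InvalidInputError("table has no confidence column")
        sub = self.data[self.data["round"] == self.rounds[0]]
        return sub.set_index("subject_id")["confidence"]


@dataclass(frozen=True)
class PriorSummary:
    """Mean/SD of log estimates before influence (natural log, n-1 SD)."""

    mu_p: float
    sigma_p: float
    n: int


@dataclass(frozen=True)
class SocialSignal:
    """The aggregate shown to subjects, in raw and log domain."""

    mode: SignalMode
    xs: float

    @property
    def mu_s(self) -> float:
        return float(np.log(self.xs))


@dataclass(frozen=True)
class SocialWeightRecord:
    """Per-individual social weight inferred from the first/second estimate.

    ``ws`` is the fraction of the log-distance toward the signal the subject
    moved; it may lie outside [0, 1] (overshooting or contrarian moves).
    ``defined`` is False when the first estimate coincides with the signal,
    which makes the weight unidentifiable.
    """

    subject_id: object
    y1: float
    y2: float
    ws: float = float("nan")
    defined: bool = True

    @property
    def wp(self) -> float:
        return 1.0 - self.ws


@dataclass(frozen=True)
class PosteriorPrediction:
    """Predicted log-estimate distribution after influence."""

    mu_f: float
    sigma_f: float
    mode: Condition


@dataclass
class PooledSample:
    """z-scored log estimates pooled across experiments."""

    z: np.ndarray
    source: list[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return self.z.size


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _positive_array(values: Iterable[float], what: str = "values") -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, (np.ndarray, pd.Series)) else values,
                     dtype=float)
    arr = np.ravel(arr)
    if arr.size == 0:
        raise InvalidInputError(f"{what} must be non-empty")
    if not np.all(arr > 0) or not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{what} must be finite and strictly positive")
    return arr


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean of strictly positive values, exp(mean(log x))."""
    arr = _positive_array(values)
    return float(np.exp(np.mean(np.log(arr))))


def social_signal(estimates: Iterable[float],
                  mode: SignalMode | str = SignalMode.GEOMETRIC) -> SocialSignal:
    """Aggregate a group's estimates into the signal shown to subjects."""
    mode = SignalMode(mode)
    arr = _positive_array(estimates, "estimates")
    if mode is SignalMode.GEOMETRIC:
        xs = float(np.exp(np.mean(np.log(arr))))
    else:
        xs = float(np.mean(arr))
    return SocialSignal(mode=mode, xs=xs)


def predict_update(x1, ws, signal: SocialSignal):
    """Second estimate predicted by the weighted geometric-mean rule.

    Accepts scalars or arrays for ``x1`` and ``ws``; the computation is done
    in the log domain, ``y2 = (1 - ws)*y1 + ws*mu_s``.
    """
    x1a = np.asarray(x1, dtype=float)
    if np.any(x1a <= 0) or not np.all(np.isfinite(x1a)):
        raise InvalidInputError("x1 must be strictly positive")
    wsa = np.asarray(ws, dtype=float)
    y2 = (1.0 - wsa) * np.log(x1a) + wsa * signal.mu_s
    out = np.exp(y2)
    return float(out) if np.isscalar(x1) and np.isscalar(ws) else out


def infer_social_weight(y1: float, y2: float, mu_s: float,
                        tol: float = EQ_TOL,
                        subject_id: object = None) -> SocialWeightRecord:
    """Invert the update rule for one subject: ws = (y2 - y1)/(mu_s - y1).

    When the private log estimate coincides with the signal (|mu_s - y1| <=
    tol) the weight is unidentifiable and the record is flagged undefined.
    """
    denom = mu_s - y1
    if abs(denom) <= tol:
        return SocialWeightRecord(subject_id=subject_id, y1=y1, y2=y2,
                                  ws=float("nan"), defined=False)
    return SocialWeightRecord(subject_id=subject_id, y1=y1, y2=y2,
                              ws=(y2 - y1) / denom, defined=True)


def social_weights(table: ExperimentTable,
                   before: int = 1, after: int = 2,
                   mode: SignalMode | str | None = None,
                   tol: float = EQ_TOL) -> list[SocialWeightRecord]:
    """Social weights of every subject present in both rounds of a table.

    The signal is computed over *all* ``before``-round estimates (the focal
    subject included) with the mode implied by the experiment's condition
    unless ``mode`` overrides it.  The no-information condition has no signal
    and raises.
    """
    if mode is None:
        if table.condition is Condition.NONE:
            raise InvalidInputError(
                "no social signal in the no-information condition; "
                "pass mode= explicitly to force one")
        mode = CONDITION_SIGNAL_MODE[table.condition]
    e1 = table.estimates(before)
    e2 = table.estimates(after)
    sig = social_signal(e1.to_numpy(), mode)
    out = []
    for sid in e1.index:
        if sid not in e2.index:
            continue
        out.append(infer_social_weight(
            float(np.log(e1[sid])), float(np.log(e2[sid])), sig.mu_s,
            tol=tol, subject_id=sid))
    return out


def prior_summary(table: ExperimentTable, round: int = 1) -> PriorSummary:
    """Mean and (n-1) SD of log estimates in one round."""
    est = table.estimates(round)
    if est.size < 2:
        raise InsufficientDataError("need at least 2 subjects")
    logs = np.log(est.to_numpy())
    return PriorSummary(mu_p=float(logs.mean()),
                        sigma_p=float(logs.std(ddof=1)),
                        n=int(est.size))


def predict_posterior(prior: PriorSummary, ws: float,
                      mode: Condition | str = Condition.FULL) -> PosteriorPrediction:
    """Population-level prediction of the log-estimate distribution after
    influence: SD shrinks to ``sigma_p*sqrt(1-ws)``; under the aggregated
    (arithmetic-mean) signal the mean also shifts by ``ws*sigma_p**2/2``.
    """
    mode = Condition(mode)
    if mode is Condition.NONE:
        raise InvalidInputError("no posterior prediction without social input")
    if ws >= 1.0:
        raise DegenerateDataError("ws >= 1 gives a degenerate (zero) variance")
    sigma_f = prior.sigma_p * float(np.sqrt(1.0 - ws))
    if mode is Condition.FULL:
        mu_f = prior.mu_p
    else:
        mu_f = prior.mu_p + ws * prior.sigma_p ** 2 / 2.0
    return PosteriorPrediction(mu_f=mu_f, sigma_f=sigma_f, mode=mode)


def zscore_pool(tables: Sequence[ExperimentTable], round: int = 2) -> PooledSample:
    """Pool estimates across experiments as z-scores of log estimates.

    Each experiment's *round-1* mean and SD standardize that experiment's
    estimates in whichever round is requested, so different groups and
    questions become comparable: round-1 pooling is N(0, 1) per experiment by
    construction and round-2 pooling exposes the influence-induced shift and
    shrinkage.
    """
    zs, src = [], []
    for t in tables:
        prior = prior_summary(t, round=1)
        if prior.sigma_p == 0:
            raise DegenerateDataError(
                f"experiment ({t.group_id}, {t.question_id}) has zero round-1 SD")
        est = t.estimates(round)
        z = (np.log(est.to_numpy()) - prior.mu_p) / prior.sigma_p
        zs.append(z)
        src.extend(((t.group_id, t.question_id, t.condition.value, sid, round)
                    for sid in est.index))
    if not zs:
        raise InsufficientDataError("no experiments to pool")
    return PooledSample(z=np.concatenate(zs), source=src)


def fit_social_weight_from_variance(pooled_after: PooledSample | np.ndarray) -> float:
    """Social weight implied by the dispersion of the pooled post-influence z.

    Inverts ``sd(z_after) = sqrt(1 - ws)``, so ``ws = 1 - sd**2``.  A pooled
    SD above 1 (dispersion *increased*) yields a negative ws, returned with a
    warning.
    """
    z = pooled_after.z if isinstance(pooled_after, PooledSample) else np.asarray(pooled_after, float)
    if z.size < 2:
        raise InsufficientDataError("need at least 2 pooled values")
    sd = float(np.std(z, ddof=1))
    ws = 1.0 - sd ** 2
    if ws < 0:
        warnings.warn("post-influence dispersion exceeds the prior dispersion; "
                      "fitted social weight is negative", stacklevel=2)
    return ws
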
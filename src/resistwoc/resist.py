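"""Extraction of the subgroup resisting social influence (the omega sweep).

Starting from the whole crowd and its geometric mean (the wisdom-of-crowds
value, WOC), individuals are eliminated one by one from highest to lowest
|ws|, keeping those with |ws| <= omega.  Each nested subgroup is scored by a
Monte-Carlo significance test: the probability that a random same-size
subset of the crowd has a geometric mean at least as far (on the log scale)
from the WOC as the subgroup's.  Three aggregators turn the sweep into a
single estimate over omega in [0, omega_max]:

* ``resist1`` -- significance-weighted average of the subgroup geometric
  means, with weight q(omega) = 0.05 - p(omega) where p < 0.05 and 0
  otherwise;
* ``resist2`` -- unweighted average over the significant omega range;
* ``resist3`` -- the subgroup at the single most significant omega.

All three are step-function integrals computed exactly: the subgroup (hence
its geometric mean and p-value) only changes at the observed distinct |ws|
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import InvalidInputError, SocialWeightRecord, geometric_mean

__all__ = ["ResistSweepPoint", "ResistResult",
           "subgroup_pvalue", "sweep_omega",
           "resist1", "resist2", "resist3", "resist_analysis"]

#: Monte-Carlo resamples used in the subgroup significance test.
DEFAULT_N_RESAMPLES = 100_000
#: Significance level defining the weight q(omega) = alpha - p(omega).
ALPHA = 0.05
#: Upper integration limit: only subgroups of sufficiently low social weight.
DEFAULT_OMEGA_MAX = 0.5

_TIE_EPS = 1e-12  # float-safe ">=" in tail counts


def subgroup_pvalue(all_estimates, k: int, observed_gm: float,
                    n_resamples: int = DEFAULT_N_RESAMPLES,
                    seed=None) -> float:
    """Significance of a size-k subgroup's geometric mean against the WOC.

    Draws ``n_resamples`` size-k subsets of the crowd without replacement
    and returns the proportion whose geometric mean is at least as far from
    the crowd's geometric mean, on the log scale, as ``observed_gm``.
    """
    x = np.ravel(np.asarray(all_estimates, dtype=float))
    n = x.size
    if n == 0 or np.any(x <= 0):
        raise InvalidInputError("estimates must be non-empty and positive")
    if not 1 <= k <= n:
        raise InvalidInputError(f"k={k} outside 1..{n}")
    if n_resamples < 1:
        raise InvalidInputError("n_resamples must be >= 1")
    logs = np.log(x)
    woc = logs.mean()
    obs = abs(float(np.log(observed_gm)) - woc)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_resamples, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_resamples:
        c = min(chunk, n_resamples - done)
        # the k smallest of iid uniform keys index a uniform random subset
        keys = rng.random((c, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        g = logs[idx].mean(axis=1)
        count += int(np.sum(np.abs(g - woc) >= obs - _TIE_EPS))
        done += c
    return count / n_resamples


@dataclass(frozen=True)
class ResistSweepPoint:
    """One nested subgroup |ws| <= omega of the sweep."""

    omega: float
    n_omega: int
    gm: float
    p: float
    member_ids: tuple = ()

    @property
    def q(self) -> float:
        return ALPHA - self.p if self.p < ALPHA else 0.0

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _aligned_inputs(weights, estimates):
    """Accept SocialWeightRecord lists or plain arrays; keep defined only."""
    if len(weights) and isinstance(weights[0], SocialWeightRecord):
        recs = [r for r in weights if r.defined]
        ws = np.array([r.ws for r in recs], dtype=float)
        ids = np.array([r.subject_id for r in recs], dtype=object)
        est = estimates
        if hasattr(est, "loc"):  # Series indexed by subject_id
            est = est.loc[list(ids)].to_numpy(dtype=float)
        else:
            if len(estimates) != len(weights):
                raise InvalidInputError("estimates must align with weights")
            est = np.asarray([e for e, r in zip(estimates, weights) if r.defined],
                             dtype=float)
    else:
        ws = np.ravel(np.asarray(weights, dtype=float))
        est = np.ravel(np.asarray(estimates, dtype=float))
        ids = np.arange(ws.size, dtype=object)
        if ws.size != est.size:
            raise InvalidInputError("weights and estimates must have equal length")
    if np.any(est <= 0):
        raise InvalidInputError("estimates must be positive")
    return ws, est, ids


def sweep_omega(weights, estimates,
                n_resamples: int = DEFAULT_N_RESAMPLES,
                seed=0, min_size: int = 1) -> list[ResistSweepPoint]:
    """Nested-subgroup sweep over the observed distinct |ws| values.

    ``weights`` may be SocialWeightRecord objects (undefined ones are
    excluded) or a plain array of social weights; ``estimates`` are the
    matching round-1 estimates (array, or Series indexed by subject id).
    Returns sweep points sorted by increasing omega, from the smallest-|ws|
    subgroup of size ``min_size`` or more up to the whole crowd.
    """
    ws, est, ids = _aligned_inputs(weights, estimates)
    if ws.size < 2:
        raise InvalidInputError("need at least 2 defined social weights")
    aws = np.abs(ws)
    omegas = np.unique(aws)  # ascending distinct |ws|
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(omegas.size)
    points = []
    for om, cs in zip(omegas, child_seeds):
        mask = aws <= om
        k = int(mask.sum())
        if k < min_size:
            continue
        gm = geometric_mean(est[mask])
        p = subgroup_pvalue(est, k, gm, n_resamples=n_resamples, seed=cs)
        points.append(ResistSweepPoint(omega=float(om), n_omega=k, gm=gm, p=p,
                                       member_ids=tuple(ids[mask])))
    return points


def _steps(sweep: Sequence[ResistSweepPoint], omega_max: float):
    """Piecewise-constant segments (width, point) covering [0, omega_max].

    The subgroup for omega in [a_j, a_{j+1}) is the sweep point at a_j; below
    the smallest observed |ws| the subgroup is empty and contributes nothing.
    """
    pts = sorted(sweep, key=lambda s: s.omega)
    segs = []
    for j, pt in enumerate(pts):
        left = pt.omega
        right = pts[j + 1].omega if j + 1 < len(pts) else np.inf
        lo, hi = left, min(right, omega_max)
        if hi > lo:
            segs.append((hi - lo, pt))
        # a point sitting exactly at omega_max still defines a zero-width step
    return segs


def resist1(sweep: Sequence[ResistSweepPoint],
            omega_max: float = DEFAULT_OMEGA_MAX) -> float | None:
    """Significance-weighted estimate: integral of q(omega)*gm(omega) over
    [0, omega_max] divided by the integral of q(omega).  None when no omega
    in range is significant."""
    num = den = 0.0
    for width, pt in _steps(sweep, omega_max):
        num += width * pt.q * pt.gm
        den += width * pt.q
    return num / den if den > 0 else None


def resist2(sweep: Sequence[ResistSweepPoint],
            omega_max: float = DEFAULT_OMEGA_MAX) -> float | None:
    """Unweighted average of gm(omega) over the significant omega range."""
    num = den = 0.0
    for width, pt in _steps(sweep, omega_max):
        if pt.significant:
            num += width * pt.gm
            den += width
    return num / den if den > 0 else None


def resist3(sweep: Sequence[ResistSweepPoint],
            omega_max: float = DEFAULT_OMEGA_MAX) -> tuple[float, float] | None:
    """(gm, omega) of the single most significant subgroup with omega in
    range; p ties are broken toward the larger subgroup (more data)."""
    cands = [pt for pt in sweep
             if pt.significant and pt.omega <= omega_max]
    if not cands:
        return None
    best = min(cands, key=lambda pt: (pt.p, -pt.n_omega))
    return best.gm, best.omega


@dataclass
class ResistResult:
    """Summary of the omega sweep and the three resist aggregators."""

    resist1: float | None
    resist2: float | None
    resist3: float | None
    resist3_omega: float | None
    significant_interval: tuple[float, float] | None
    members_at_best: tuple = ()
    sweep: list[ResistSweepPoint] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "resist1": self.resist1,
            "resist2": self.resist2,
            "resist3": self.resist3,
            "resist3_omega": self.resist3_omega,
            "significant_interval": self.significant_interval,
            "members_at_best": list(self.members_at_best),
            "sweep": [{"omega": s.omega, "n": s.n_omega, "gm": s.gm,
                       "p": s.p, "q": s.q} for s in self.sweep],
        }


def resist_analysis(weights, estimates,
                    n_resamples: int = DEFAULT_N_RESAMPLES,
                    seed=0, omega_max: float = DEFAULT_OMEGA_MAX,
                    min_size: int = 1) -> ResistResult:
    """Run the full sweep and all three resist aggregators."""
    sweep = sweep_omega(weights, estimates, n_resamples=n_resamples,
                        seed=seed, min_size=min_size)
    sig = [pt for pt in sweep if pt.significant and pt.omega <= omega_max]
    interval = (min(pt.omega for pt in sig), max(pt.omega for pt in sig)) if sig else None
    r3 = resist3(sweep, omega_max)
    members = ()
    if r3 is not None:
        best = next(pt for pt in sweep if pt.omega == r3[1])
        members = best.member_ids
    return ResistResult(
        resist1=resist1(sweep, omega_max),
        resist2=resist2(sweep, omega_max),
        resist3=r3[0] if r3 else None,
        resist3_omega=r3[1] if r3 else None,
        significant_interval=interval,
        members_at_best=members,
        sweep=sweep,
    )
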
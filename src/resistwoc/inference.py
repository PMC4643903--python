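"""Resampling significance machinery.

Three tests support the analysis:

* a permutation test for a difference of means or variances between two
  samples (the pooled z-scores before vs after influence): the samples are
  mixed, randomly re-split preserving the original sizes, and the p-value is
  the proportion of permuted absolute differences at least as large as the
  observed one;
* an exact hypergeometric upper-tail test for whether two subject subsets
  drawn from the same finite population share at least ``m`` members (do the
  same individuals resist influence across questions?);
* the declared-confidence control: the subgroup machinery of the omega
  sweep applied to subjects declaring confidence >= kappa, for kappa = 1..6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core import ExperimentTable, InvalidInputError, geometric_mean
from .resist import DEFAULT_N_RESAMPLES, subgroup_pvalue

__all__ = ["PermutationTestResult", "permutation_test_diff",
           "overlap_pvalue", "ConfidenceSweepPoint", "confidence_extraction"]

DEFAULT_N_PERMUTATIONS = 1_000_000
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: str
    observed: float
    p: float
    n_permutations: int
    seed: object

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "observed": self.observed,
                "p": self.p, "n_permutations": self.n_permutations,
                "seed": self.seed}


def _group_stats(s: np.ndarray, ss: np.ndarray, n: int, statistic: str):
    if statistic == "mean":
        return s / n
    # sample (n-1) variance from sums and sums of squares
    return (ss - s * s / n) / (n - 1)


def permutation_test_diff(a, b, statistic: str = "mean",
                          n_permutations: int = DEFAULT_N_PERMUTATIONS,
                          seed=0) -> PermutationTestResult:
    """Permutation test of |theta(a) - theta(b)| for theta = mean or variance.

    The two samples are pooled and randomly re-partitioned into groups of
    the original sizes; p is the proportion of permuted differences >= the
    observed difference (ties count, so p is never 0).
    """
    if statistic not in ("mean", "variance"):
        raise InvalidInputError("statistic must be 'mean' or 'variance'")
    a = np.ravel(np.asarray(a, dtype=float))
    b = np.ravel(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("both samples need at least 2 values")
    pooled = np.concatenate([a, b])
    n, n1, n2 = pooled.size, a.size, b.size
    tot_s, tot_ss = pooled.sum(), (pooled ** 2).sum()
    obs = abs(_group_stats(a.sum(), (a ** 2).sum(), n1, statistic)
              - _group_stats(b.sum(), (b ** 2).sum(), n2, statistic))
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_permutations, 10_000_000 // n))
    done = 0
    sq = pooled ** 2
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        keys = rng.random((c, n))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        s1 = pooled[idx].sum(axis=1)
        ss1 = sq[idx].sum(axis=1)
        t1 = _group_stats(s1, ss1, n1, statistic)
        t2 = _group_stats(tot_s - s1, tot_ss - ss1, n2, statistic)
        count += int(np.sum(np.abs(t1 - t2) >= obs - _TIE_EPS))
        done += c
    return PermutationTestResult(statistic=statistic, observed=float(obs),
                                 p=count / n_permutations,
                                 n_permutations=n_permutations, seed=seed)


def overlap_pvalue(n_pop: int, k1: int, k2: int, m: int) -> float:
    """P(two random subsets of sizes k1, k2 from n_pop share >= m members).

    Exact upper-tail hypergeometric probability: conditioning on the first
    subset, the overlap of the second is hypergeometric(n_pop, k1, k2).
    """
    if not (0 <= k1 <= n_pop and 0 <= k2 <= n_pop):
        raise InvalidInputError("subset sizes must lie in 0..n_pop")
    lo = max(0, k1 + k2 - n_pop)
    hi = min(k1, k2)
    if not lo <= m <= hi:
        raise InvalidInputError(f"overlap m={m} infeasible (range {lo}..{hi})")
    return float(hypergeom.sf(m - 1, n_pop, k1, k2))


@dataclass(frozen=True)
class ConfidenceSweepPoint:
    """Subgroup declaring confidence >= kappa."""

    kappa: int
    n: int
    gm: float
    p: float


def confidence_extraction(table: ExperimentTable,
                          n_resamples: int = DEFAULT_N_RESAMPLES,
                          seed=0) -> list[ConfidenceSweepPoint]:
    """Declared-confidence analogue of the omega sweep (negative control).

    For each kappa in 1..6, the geometric mean of round-1 estimates of the
    subjects declaring confidence >= kappa and its Monte-Carlo significance
    against the crowd's geometric mean.  Levels with no subjects are
    omitted.
    """
    conf = table.confidences()
    if conf.isna().any():
        raise InvalidInputError("confidence missing for some subjects")
    conf = conf.astype(float)
    if ((conf < 1) | (conf > 6)).any():
        raise InvalidInputError("confidence must lie in 1..6")
    est = table.estimates(table.rounds[0]).loc[conf.index].to_numpy()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(6)
    out = []
    for kappa, cs in zip(range(1, 7), seeds):
        mask = (conf >= kappa).to_numpy()
        k = int(mask.sum())
        if k == 0:
            continue
        gm = geometric_mean(est[mask])
        p = subgroup_pvalue(est, k, gm, n_resamples=n_resamples, seed=cs)
        out.append(ConfidenceSweepPoint(kappa=kappa, n=k, gm=gm, p=p))
    return out
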
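"""CSV ingestion, validation and the end-to-end analysis pipeline.

The on-disk dialect is a UTF-8 CSV with a header row and columns
``subject_id, group_id, question_id, condition, round, estimate`` plus
optional ``confidence`` and ``truth`` (one value per question).  Source
files with different column names are mapped via ``column_map``.  Rows with
non-positive or non-numeric estimates are rejected with line-numbered
diagnostics (line 1 is the header).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import inference as _inference
from . import resist as _resist
from .core import (Condition, ExperimentTable, InsufficientDataError,
                   InvalidInputError, fit_social_weight_from_variance,
                   geometric_mean, predict_posterior, prior_summary,
                   social_weights, zscore_pool)
from .density import DensityConfig

__all__ = ["REQUIRED_COLUMNS", "read_estimations", "write_estimations",
           "RunConfig", "run_pipeline", "write_report"]

REQUIRED_COLUMNS = ("subject_id", "group_id", "question_id", "condition",
                    "round", "estimate")
OPTIONAL_COLUMNS = ("confidence", "truth")


def read_estimations(path, column_map: dict[str, str] | None = None
                     ) -> list[ExperimentTable]:
    """Read and validate a CSV of estimation records.

    ``column_map`` maps this package's column names to the file's (e.g.
    ``{"estimate": "E1"}``) so unstandardized source layouts can be ingested
    without editing the file.  Returns one ExperimentTable per
    (group, question, condition) cell.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    # header is line 1; first data row is line 2
    lines = df.index.to_numpy() + 2
    est = pd.to_numeric(df["estimate"], errors="coerce")
    bad = est.isna() | (est <= 0)
    if bad.any():
        where = ", ".join(str(ln) for ln in lines[bad.to_numpy()][:20])
        raise InvalidInputError(
            f"{path}: non-positive or non-numeric estimate on line(s) {where}")
    df["estimate"] = est
    rnd = pd.to_numeric(df["round"], errors="coerce")
    if rnd.isna().any() or (rnd < 1).any():
        raise InvalidInputError(f"{path}: round must be a positive integer")
    df["round"] = rnd.astype(int)
    dup = df.duplicated(["subject_id", "group_id", "question_id",
                         "condition", "round"])
    if dup.any():
        where = ", ".join(str(ln) for ln in lines[dup.to_numpy()][:20])
        raise InvalidInputError(f"{path}: duplicate subject/round rows on line(s) {where}")
    try:
        conditions = df["condition"].map(Condition)
    except ValueError as exc:
        raise InvalidInputError(f"{path}: unknown condition value ({exc})") from exc
    df["condition"] = conditions
    tables = []
    for (gid, qid, cond), sub in df.groupby(
            ["group_id", "question_id", "condition"], sort=True, observed=True):
        truth = None
        if "truth" in sub.columns:
            tvals = pd.to_numeric(sub["truth"], errors="coerce").dropna().unique()
            if tvals.size > 1:
                raise InvalidInputError(
                    f"{path}: conflicting truth values for question {qid}")
            if tvals.size == 1:
                truth = float(tvals[0])
        cols = ["subject_id", "round", "estimate"]
        if "confidence" in sub.columns:
            cols.append("confidence")
        tables.append(ExperimentTable(data=sub[cols].reset_index(drop=True),
                                      group_id=str(gid), question_id=str(qid),
                                      condition=cond, truth=truth))
    return tables


def write_estimations(tables: Sequence[ExperimentTable], path) -> None:
    """Write tables back to the same CSV dialect (round-trips with
    ``read_estimations``)."""
    frames = []
    for t in tables:
        d = t.data.copy()
        d["group_id"] = t.group_id
        d["question_id"] = t.question_id
        d["condition"] = t.condition.value
        if t.truth is not None:
            d["truth"] = t.truth
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    lead = [c for c in REQUIRED_COLUMNS if c in out.columns]
    rest = [c for c in out.columns if c not in lead]
    out[lead + rest].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    input_path: object = None
    condition_filter: tuple[str, ...] | None = None
    rounds: tuple[int, int] = (1, 2)
    n_resamples: int = _resist.DEFAULT_N_RESAMPLES
    n_permutations: int = _inference.DEFAULT_N_PERMUTATIONS
    seed: int = 0
    gamma_ws_values: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0)
    omega_max: float = _resist.DEFAULT_OMEGA_MAX
    min_subgroup_size: int = 1
    density: DensityConfig = field(default_factory=DensityConfig)
    column_map: dict | None = None

    def __post_init__(self) -> None:
        if self.rounds[0] == self.rounds[1]:
            raise InvalidInputError("round pair must be distinct")
        if min(self.n_resamples, self.n_permutations) < 1:
            raise InvalidInputError("resample counts must be positive")


def _unit_prior(n: int):
    """Standard-normal prior of the pooled z-scores (mean 0, SD 1)."""
    from .core import PriorSummary
    return PriorSummary(mu_p=0.0, sigma_p=1.0, n=n)


def _question_analysis(tables: list[ExperimentTable], cfg: RunConfig,
                       seed_seq: np.random.SeedSequence) -> dict:
    """Analysis of one (question, condition) cell, pooling its groups.

    Social weights are inferred per group (each group saw its own signal);
    weights and round-1 estimates are then pooled across the question's
    groups for the sweep and the clustering, mirroring the per-question
    analyses of multi-group studies.
    """
    before, after = cfg.rounds
    ws, est, ids = [], [], []
    n_undefined = 0
    for t in tables:
        e1 = t.estimates(before)
        for rec in social_weights(t, before=before, after=after):
            if not rec.defined:
                n_undefined += 1
                continue
            ws.append(rec.ws)
            est.append(float(e1[rec.subject_id]))
            ids.append(f"{t.group_id}:{rec.subject_id}")
    out: dict = {
        "n_subjects": len(ws) + n_undefined,
        "n_undefined_ws": n_undefined,
        "woc": geometric_mean(est) if est else None,
        "truth": tables[0].truth,
    }
    if len(ws) < 2:
        out["note"] = "fewer than 2 defined social weights; sweep skipped"
        return out
    s_resist, s_cluster = seed_seq.spawn(2)
    res = _resist.resist_analysis(np.asarray(ws), np.asarray(est),
                                  n_resamples=cfg.n_resamples, seed=s_resist,
                                  omega_max=cfg.omega_max,
                                  min_size=cfg.min_subgroup_size)
    out["resist"] = res.to_dict()
    clusters = {}
    for g_ws, s in zip(cfg.gamma_ws_values,
                       s_cluster.spawn(len(cfg.gamma_ws_values))):
        try:
            ana = _cluster.cluster_analysis(
                np.asarray(ws), np.asarray(est), member_ids=np.asarray(ids, object),
                config=cfg.density, gamma_ws=g_ws,
                seed=int(s.generate_state(1)[0] % 2**31))
            clusters[str(g_ws)] = {"low": ana["low"].to_dict(),
                                   "high": ana["high"].to_dict()}
        except Exception as exc:  # noqa: BLE001 -- cell-level failure is data-dependent
            clusters[str(g_ws)] = {"error": f"{type(exc).__name__}: {exc}"}
    out["clusters"] = clusters
    return out


def run_pipeline(tables: Sequence[ExperimentTable] | None = None,
                 config: RunConfig | None = None) -> dict:
    """Full analysis: condition-level distribution checks plus per-question
    subgroup extraction.  Returns a JSON-serializable report."""
    cfg = config or RunConfig()
    if tables is None:
        if cfg.input_path is None:
            raise InvalidInputError("either tables or config.input_path required")
        tables = read_estimations(cfg.input_path, column_map=cfg.column_map)
    if cfg.condition_filter:
        keep = {Condition(c) for c in cfg.condition_filter}
        tables = [t for t in tables if t.condition in keep]
    if not tables:
        raise InsufficientDataError("no experiments after filtering")
    root = np.random.SeedSequence(cfg.seed)
    report: dict = {
        "settings": {
            "rounds": list(cfg.rounds), "n_resamples": cfg.n_resamples,
            "n_permutations": cfg.n_permutations, "seed": cfg.seed,
            "gamma_ws_values": list(cfg.gamma_ws_values),
            "omega_max": cfg.omega_max,
        },
        "conditions": {},
        "questions": {},
    }
    before, after = cfg.rounds
    by_cond: dict[Condition, list[ExperimentTable]] = {}
    for t in tables:
        by_cond.setdefault(t.condition, []).append(t)
    s_cond = root.spawn(len(by_cond))
    for (cond, ts), scs in zip(sorted(by_cond.items(), key=lambda kv: kv[0].value),
                               s_cond):
        z1 = zscore_pool(ts, round=before)
        z2 = zscore_pool(ts, round=after)
        s_mean, s_var = scs.spawn(2)
        entry: dict = {
            "n_experiments": len(ts),
            "z_before": {"mean": float(z1.z.mean()), "sd": float(z1.z.std(ddof=1))},
            "z_after": {"mean": float(z2.z.mean()), "sd": float(z2.z.std(ddof=1))},
            "mean_change_test": _inference.permutation_test_diff(
                z1.z, z2.z, "mean", n_permutations=cfg.n_permutations,
                seed=int(s_mean.generate_state(1)[0] % 2**31)).to_dict(),
            "variance_change_test": _inference.permutation_test_diff(
                z1.z, z2.z, "variance", n_permutations=cfg.n_permutations,
                seed=int(s_var.generate_state(1)[0] % 2**31)).to_dict(),
        }
        if cond is Condition.NONE:
            entry["note"] = "no influence; change tests only"
        else:
            fitted = fit_social_weight_from_variance(z2)
            entry["fitted_ws"] = fitted
            mean_sigma_p = float(np.mean(
                [prior_summary(t, round=before).sigma_p for t in ts]))
            entry["mean_sigma_p"] = mean_sigma_p
            if fitted < 1.0:
                unit_prior = predict_posterior(
                    _unit_prior(len(z1)), fitted, cond)
                entry["predicted_z_sd"] = unit_prior.sigma_f
                if cond is Condition.AGGREGATED:
                    entry["predicted_z_shift"] = fitted * mean_sigma_p / 2.0
        report["conditions"][cond.value] = entry
    # per-question extraction, only where a social signal existed
    by_q: dict[tuple[str, str], list[ExperimentTable]] = {}
    for t in tables:
        if t.condition is Condition.NONE:
            continue
        by_q.setdefault((t.question_id, t.condition.value), []).append(t)
    s_q = root.spawn(len(by_q) + 1)[1:]
    for (key, ts), sq in zip(sorted(by_q.items()), s_q):
        qid, cond = key
        report["questions"][f"{qid}/{cond}"] = _question_analysis(ts, cfg, sq)
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
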
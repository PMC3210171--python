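"""Survival-driven classifier training.

The training loop mirrors how the automated CTC definition was found:
candidate features are screened by the hazard ratio they produce on their
own, classifier bounds are grid-searched against a multi-criterion objective
(high baseline and follow-up HR, follow-up HR above baseline HR, and a low
absolute and relative count in healthy controls), and the stability of the
winning bounds is assessed by bootstrap aggregation over patients.

During the search patients are dichotomized at the cohort median count,
which balances the at-risk and not-at-risk groups and keeps HR estimates
comparable across candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import Classifier, Rule, accepted_volume, classify_table
from .survival import _efron_fit, dichotomize


@dataclass(frozen=True)
class BoundGrid:
    """Candidate bounds for one feature: a rule kind and an ordered grid.

    For ``kind`` "gt" or "lt" each value is a scalar bound; for "range" each
    value is a ``(low, high)`` pair.
    """

    kind: str  # "gt" | "lt" | "range"
    values: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("gt", "lt", "range"):
            raise ValueError("kind must be gt, lt or range")
        if len(self.values) == 0:
            raise ValueError("grid must be non-empty")

    def rules(self) -> list[Rule]:
        if self.kind == "gt":
            return [Rule(gt=float(v)) for v in self.values]
        if self.kind == "lt":
            return [Rule(lt=float(v)) for v in self.values]
        return [Rule(low=float(lo), high=float(hi)) for lo, hi in self.values]


@dataclass(frozen=True)
class SearchSpace:
    """Finite grid over classifier bounds, one :class:`BoundGrid` per feature."""

    grids: dict[str, BoundGrid]

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("search space must contain at least one feature")

    def candidates(self) -> list[Classifier]:
        feats = list(self.grids)
        rule_lists = [self.grids[f].rules() for f in feats]
        out = []
        for i, combo in enumerate(itertools.product(*rule_lists)):
            out.append(Classifier(name=f"cand{i:05d}", rules=dict(zip(feats, combo))))
        return out


@dataclass
class ObjectiveConfig:
    """Objective weights and feasibility bounds.

    Feasibility is hard: follow-up HR must exceed baseline HR by the margin,
    the absolute control count may not exceed ``max_control_total`` over the
    whole control set, and the relative control level (mean control count /
    mean baseline patient count) may not exceed ``max_control_relative``.
    Among feasible candidates the score ``w_baseline * hr_baseline +
    w_followup * hr_followup`` is maximized.
    """

    w_baseline: float = 1.0
    w_followup: float = 1.0
    followup_margin: float = 0.0
    max_control_total: float = 1.0
    max_control_relative: float = 0.02


@dataclass(frozen=True)
class ObjectiveResult:
    hr_baseline: float
    hr_followup: float
    control_total: int
    control_relative: float
    feasible: bool
    score: float


@dataclass
class GridSearchResult:
    """Winner (or ``None`` when no candidate is feasible) plus diagnostics."""

    classifier: Classifier | None
    objective: ObjectiveResult | None
    n_candidates: int
    n_feasible: int
    table: pd.DataFrame  # per-candidate evaluation


class _CountingSet:
    """Feature table pre-indexed for fast per-candidate counting."""

    def __init__(self, features: pd.DataFrame, sample_ids: list[str]):
        self.features = features.reset_index(drop=True)
        self.sample_ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        self.index = features["sample_id"].map(pos).to_numpy(dtype=np.int64)
        self.n = len(self.sample_ids)

    def counts(self, classifier: Classifier) -> np.ndarray:
        mask = classify_table(self.features, classifier)
        return np.bincount(self.index[mask], minlength=self.n)


def _median_split_hr(counts: np.ndarray, times, events, cache: dict) -> float:
    """HR of the median-dichotomized count groups, by the fast in-module
    Efron Newton solver (it agrees with the full fit and keeps the grid
    search cheap)."""
    key = counts.tobytes()
    if key in cache:
        return cache[key]
    group, _ = dichotomize(counts)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if group.all() or not group.any() or e.sum() == 0:
        hr = float("nan")
    elif e[group == 0].sum() == 0 or e[group == 1].sum() == 0:
        hr = float("nan")  # monotone likelihood
    else:
        beta, se = _efron_fit(t, e, group.astype(float))
        hr = float(np.exp(beta)) if np.isfinite(se) else float("nan")
    cache[key] = hr
    return hr


def _observed_ranges(tables: list[pd.DataFrame], feats: list[str]) -> dict:
    ranges = {}
    for f in feats:
        vals = np.concatenate([t[f].to_numpy(dtype=float) for t in tables if f in t])
        ranges[f] = (float(vals.min()), float(vals.max()))
    return ranges


def grid_search(
    space: SearchSpace,
    baseline: tuple[pd.DataFrame, pd.DataFrame],
    followup: tuple[pd.DataFrame, pd.DataFrame],
    controls: pd.DataFrame,
    n_control_samples: int,
    objective: ObjectiveConfig | None = None,
) -> GridSearchResult:
    """Exhaustive threshold-box search against the survival objective.

    ``baseline`` and ``followup`` are ``(feature_table, cohort)`` pairs with a
    shared ``sample_id`` patient key; ``controls`` is a feature table over
    healthy samples.  The winner maximizes the objective score among feasible
    candidates; ties break toward the stricter classifier (smaller accepted
    feature volume), then toward earlier lexicographic grid order.
    """
    obj_cfg = objective or ObjectiveConfig()
    b_feats, b_cohort = baseline
    f_feats, f_cohort = followup
    ids = list(b_cohort["sample_id"])
    if set(ids) != set(f_cohort["sample_id"]):
        raise ValueError("baseline and follow-up cohorts must share patient ids")

    b_set = _CountingSet(b_feats, ids)
    f_set = _CountingSet(f_feats, list(f_cohort["sample_id"]))
    c_index = None
    if len(controls):
        ctl_ids = list(dict.fromkeys(controls["sample_id"]))
        c_set = _CountingSet(controls, ctl_ids)
    else:
        c_set = None

    bt = b_cohort["os_months"].to_numpy(float)
    be = b_cohort["event"].to_numpy(int)
    ft = f_cohort["os_months"].to_numpy(float)
    fe = f_cohort["event"].to_numpy(int)

    feats = list(space.grids)
    ranges = _observed_ranges([b_feats, f_feats] + ([controls] if len(controls) else []), feats)

    candidates = space.candidates()
    b_cache: dict = {}
    f_cache: dict = {}
    mean_baseline_count = None
    rows = []
    best = None  # (score, -volume, -order_index, candidate_idx)
    for i, cand in enumerate(candidates):
        b_counts = b_set.counts(cand)
        f_counts = f_set.counts(cand)
        ctl_total = int(c_set.counts(cand).sum()) if c_set is not None else 0
        hr_b = _median_split_hr(b_counts, bt, be, b_cache)
        hr_f = _median_split_hr(f_counts, ft, fe, f_cache)
        mean_b = float(b_counts.mean())
        ctl_mean = ctl_total / max(n_control_samples, 1)
        rel = ctl_mean / mean_b if mean_b > 0 else np.inf if ctl_total else 0.0
        feasible = (
            np.isfinite(hr_b)
            and np.isfinite(hr_f)
            and hr_f > hr_b * (1.0 + obj_cfg.followup_margin)
            and ctl_total <= obj_cfg.max_control_total
            and rel <= obj_cfg.max_control_relative
        )
        score = (
            obj_cfg.w_baseline * hr_b + obj_cfg.w_followup * hr_f
            if feasible
            else float("nan")
        )
        res = ObjectiveResult(
            hr_baseline=hr_b, hr_followup=hr_f, control_total=ctl_total,
            control_relative=rel, feasible=bool(feasible), score=score,
        )
        row = {"candidate": i, **{f: cand.rules[f].to_json() for f in feats},
               "hr_baseline": hr_b, "hr_followup": hr_f,
               "control_total": ctl_total, "control_relative": rel,
               "feasible": bool(feasible), "score": score}
        rows.append(row)
        if feasible:
            vol = accepted_volume(cand, ranges)
            key = (score, -vol, -i)
            if best is None or key > best[0]:
                best = (key, cand, res)

    table = pd.DataFrame(rows)
    n_feas = int(table["feasible"].sum())
    if best is None:
        return GridSearchResult(
            classifier=None, objective=None,
            n_candidates=len(candidates), n_feasible=0, table=table,
        )
    return GridSearchResult(
        classifier=best[1], objective=best[2],
        n_candidates=len(candidates), n_feasible=n_feas, table=table,
    )


# ---------------------------------------------------------------------------
# feature screening


def rank_features(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    candidate_features: list[str] | None = None,
    corr_threshold: float = 0.8,
) -> pd.DataFrame:
    """Screen candidate features by single-feature hazard ratio.

    Each feature is scored by the HR obtained when per-sample counts of
    objects above the feature's overall median are dichotomized at the cohort
    median.  Features are then greedily selected in HR order, skipping any
    whose absolute object-level Pearson correlation with an already-selected
    feature exceeds ``corr_threshold``.  Degenerate (constant) features get
    an undefined HR and rank last.
    """
    if candidate_features is None:
        candidate_features = [
            c for c in features.columns if c not in ("sample_id", "object_id", "tile", "y", "x")
        ]
    if len(candidate_features) == 0:
        raise ValueError("need at least one candidate feature")
    ids = list(cohort["sample_id"])
    cset = _CountingSet(features, ids)
    t = cohort["os_months"].to_numpy(float)
    e = cohort["event"].to_numpy(int)

    hrs = {}
    for feat in candidate_features:
        col = features[feat].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            hrs[feat] = float("nan")
            continue
        passing = col > np.median(col)
        counts = np.bincount(cset.index[passing], minlength=cset.n)
        hrs[feat] = _median_split_hr(counts, t, e, {})

    order = sorted(
        candidate_features,
        key=lambda f: (-(hrs[f]) if np.isfinite(hrs[f]) else np.inf),
    )
    selected: list[str] = []
    sel_flags = {}
    for feat in order:
        if not np.isfinite(hrs[feat]):
            sel_flags[feat] = False
            continue
        col = features[feat].to_numpy(dtype=float)
        redundant = False
        for prev in selected:
            r = np.corrcoef(col, features[prev].to_numpy(dtype=float))[0, 1]
            if np.isfinite(r) and abs(r) > corr_threshold:
                redundant = True
                break
        if not redundant:
            selected.append(feat)
        sel_flags[feat] = not redundant
    return pd.DataFrame(
        {"feature": order,
         "hr": [hrs[f] for f in order],
         "selected": [sel_flags[f] for f in order]}
    )


# ---------------------------------------------------------------------------
# bootstrap aggregation


@dataclass
class BootstrapResult:
    """Per-replicate winning bounds and their spread."""

    bounds: pd.DataFrame  # one row per successful replicate
    spread: pd.Series  # std of each bound column
    n_skipped: int


def _bound_values(classifier: Classifier) -> dict[str, float]:
    out = {}
    for feat, rule in classifier.rules.items():
        if rule.gt is not None:
            out[feat] = rule.gt
        elif rule.lt is not None:
            out[feat] = rule.lt
        else:
            out[f"{feat}_low"] = rule.low
            out[f"{feat}_high"] = rule.high
    return out


def _resample(
    features: pd.DataFrame, cohort: pd.DataFrame, ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    by_id = {s: g for s, g in features.groupby("sample_id")}
    cohort_idx = cohort.set_index("sample_id")
    feat_parts, cohort_rows = [], []
    empty = features.iloc[0:0]
    for k, sid in enumerate(ids):
        new_id = f"r{k:05d}"
        part = by_id.get(sid, empty).copy()
        part["sample_id"] = new_id
        feat_parts.append(part)
        row = cohort_idx.loc[sid].to_dict()
        row["sample_id"] = new_id
        cohort_rows.append(row)
    feats = pd.concat(feat_parts, ignore_index=True) if feat_parts else empty
    return feats, pd.DataFrame(cohort_rows)


def bootstrap_stability(
    space: SearchSpace,
    baseline: tuple[pd.DataFrame, pd.DataFrame],
    followup: tuple[pd.DataFrame, pd.DataFrame],
    controls: pd.DataFrame,
    n_control_samples: int,
    n_boot: int,
    seed: int,
    objective: ObjectiveConfig | None = None,
    identity_first: bool = False,
) -> BootstrapResult:
    """Bootstrap-aggregate the grid search over patient-level resamples.

    Each replicate resamples patients (not objects) with replacement in both
    cohorts jointly and re-runs :func:`grid_search`; replicates with zero
    events or no feasible candidate are skipped and counted.  Deterministic
    for a fixed seed.  ``identity_first`` forces the first replicate to be
    the un-resampled cohort (a self-check: it must reproduce the full-data
    winner).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    b_feats, b_cohort = baseline
    f_feats, f_cohort = followup
    ids = list(b_cohort["sample_id"])

    rows = []
    n_skipped = 0
    for b in range(n_boot):
        if identity_first and b == 0:
            chosen = ids
        else:
            chosen = list(rng.choice(ids, size=len(ids), replace=True))
        rb = _resample(b_feats, b_cohort, chosen)
        rf = _resample(f_feats, f_cohort, chosen)
        if rb[1]["event"].sum() == 0 or rf[1]["event"].sum() == 0:
            n_skipped += 1
            continue
        res = grid_search(
            space, rb, rf, controls, n_control_samples, objective=objective
        )
        if res.classifier is None:
            n_skipped += 1
            continue
        rows.append({"replicate": b, **_bound_values(res.classifier)})
    bounds = pd.DataFrame(rows)
    value_cols = [c for c in bounds.columns if c != "replicate"]
    spread = (
        bounds[value_cols].std(ddof=0)
        if len(bounds)
        else pd.Series(dtype=float)
    )
    return BootstrapResult(bounds=bounds, spread=spread, n_skipped=n_skipped)
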
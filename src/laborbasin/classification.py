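"""Exhaustive classifier construction and assessment.

For every way of choosing half the IL and half the NIL samples as a training
set (C(10,5)*C(8,4) = 17,640 partitions for the 18-sample cohort), three
classifier families are built and scored on the held-out samples:

* model classifiers (6): nonparametric 95 % confidence intervals about the
  group medians of the basin-of-attraction labor probabilities under one of
  the six predictors;
* single-gene null classifiers (5): the same intervals on one gene's
  normalized expression;
* two-gene null classifiers (10): per-group rectangles formed as the
  Cartesian product of two genes' intervals.

A classifier is *constructed* only when its two group regions separate
(closed regions disjoint; shared endpoints count as overlap).  Test samples
are called IL, NIL or no-call by region membership, and scored by

    precision = correctly classified / total classified
    recall    = classified / total test samples
    F         = 2*precision*recall / (precision + recall)

The classifier success rate (CSR) of a configuration is the fraction of
training partitions for which it could be constructed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import (
    Cohort,
    Predictor,
    SURROGATE_GENES,
    all_predictors,
    parameterize,
)
from .labor_probability import BasinGridSpec, basin_probability
from .ode_model import LaborBasinError

__all__ = [
    "Partition",
    "IntervalPair",
    "RectanglePair",
    "ClassifierOutcome",
    "SweepConfig",
    "SweepResult",
    "CohortShapeError",
    "SampleSizeError",
    "ClassifierUsageError",
    "enumerate_partitions",
    "nonparametric_ci",
    "ci_seed",
    "construct_model_classifier",
    "construct_null_1gene",
    "construct_null_2gene",
    "classify_sample",
    "evaluate",
    "sample_probabilities",
    "sweep",
]

DEFAULT_N_BOOT = 10_000
DEFAULT_CI_LEVEL = 0.95


class CohortShapeError(LaborBasinError):
    """Cohort group sizes do not admit the requested partitioning."""


class SampleSizeError(LaborBasinError):
    """Too few values to form a confidence interval."""


class ClassifierUsageError(LaborBasinError):
    """An unconstructed classifier was asked to classify."""


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """One train/test split: half of each group trains, the rest tests."""

    train_il: tuple[str, ...]
    train_nil: tuple[str, ...]
    test: tuple[str, ...]


def _train_size(n: int) -> int:
    # half/half rule; ceil for odd group sizes
    return math.ceil(n / 2)


def enumerate_partitions(cohort: Cohort) -> list[Partition]:
    """All train/test partitions, in deterministic lexicographic order.

    Training sets take ceil(n/2) samples of each group (5 of 10 IL and
    4 of 8 NIL for the 18-sample cohort, giving 17,640 partitions); sample
    ids are sorted, and IL subsets vary slowest.
    """
    il = cohort.ids_in_group("IL")
    nil = cohort.ids_in_group("NIL")
    if len(il) < 2 or len(nil) < 2:
        raise CohortShapeError(
            f"need at least 2 samples per group, got {len(il)} IL / {len(nil)} NIL"
        )
    out = []
    all_ids = set(il) | set(nil)
    for train_il in combinations(il, _train_size(len(il))):
        for train_nil in combinations(nil, _train_size(len(nil))):
            test = tuple(sorted(all_ids - set(train_il) - set(train_nil)))
            out.append(Partition(train_il=train_il, train_nil=train_nil, test=test))
    return out


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def ci_seed(master_seed: int, kind: str, group: str, subset: Sequence[str]) -> int:
    """Deterministic bootstrap seed for one (score kind, group, subset).

    Stable hashing makes the sweep reproducible independently of evaluation
    order, and gives identical intervals to every partition that shares a
    training subset.
    """
    token = f"{master_seed}|{kind}|{group}|{','.join(subset)}"
    digest = hashlib.sha256(token.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def nonparametric_ci(
    values: Sequence[float],
    level: float = DEFAULT_CI_LEVEL,
    method: str = "bootstrap-median",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> tuple[float, float]:
    """Nonparametric confidence interval about the median of ``values``.

    ``"bootstrap-median"`` (default) is the percentile interval of the sample
    median over ``n_boot`` resamples drawn with the given seed;
    ``"range"`` is the (min, max) order-statistic interval.  Both are closed.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise SampleSizeError(f"need at least 2 values, got {vals.size}")
    if method == "range":
        return float(vals.min()), float(vals.max())
    if method != "bootstrap-median":
        raise ValueError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    medians = np.median(vals[idx], axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(medians, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    # closed intervals; a shared endpoint counts as overlap (conservative)
    return a[1] < b[0] or b[1] < a[0]


@dataclass(frozen=True)
class IntervalPair:
    """Group confidence intervals on one score axis."""

    il_interval: tuple[float, float]
    nil_interval: tuple[float, float]

    def __post_init__(self):
        for name, (lo, hi) in (("il", self.il_interval), ("nil", self.nil_interval)):
            if lo > hi:
                raise ValueError(f"{name}_interval has lower > upper: ({lo}, {hi})")

    @property
    def separated(self) -> bool:
        return _disjoint(self.il_interval, self.nil_interval)


@dataclass(frozen=True)
class RectanglePair:
    """Per-group axis-aligned confidence rectangles over two score axes."""

    il_region: tuple[tuple[float, float], tuple[float, float]]
    nil_region: tuple[tuple[float, float], tuple[float, float]]

    @property
    def separated(self) -> bool:
        # product rectangles are disjoint iff they are disjoint on some axis
        return _disjoint(self.il_region[0], self.nil_region[0]) or _disjoint(
            self.il_region[1], self.nil_region[1]
        )


def _group_interval(
    scores: Mapping[str, float],
    subset: Sequence[str],
    kind: str,
    group: str,
    *,
    method: str,
    n_boot: int,
    master_seed: int,
) -> tuple[float, float]:
    seed = ci_seed(master_seed, kind, group, tuple(subset))
    return nonparametric_ci(
        [scores[sid] for sid in subset], method=method, n_boot=n_boot, seed=seed
    )


def construct_model_classifier(
    partition: Partition,
    predictor: Predictor,
    probabilities: Mapping[str, float],
    *,
    method: str = "bootstrap-median",
    n_boot: int = DEFAULT_N_BOOT,
    master_seed: int = 0,
) -> IntervalPair:
    """Group intervals on the labor probabilities of the training samples.

    The classifier is usable only when ``result.separated``; failure to
    separate is a value, not an error.
    """
    kind = f"model:{predictor.name}"
    return IntervalPair(
        il_interval=_group_interval(
            probabilities, partition.train_il, kind, "IL",
            method=method, n_boot=n_boot, master_seed=master_seed,
        ),
        nil_interval=_group_interval(
            probabilities, partition.train_nil, kind, "NIL",
            method=method, n_boot=n_boot, master_seed=master_seed,
        ),
    )


def construct_null_1gene(
    partition: Partition,
    gene: str,
    cohort: Cohort,
    *,
    method: str = "bootstrap-median",
    n_boot: int = DEFAULT_N_BOOT,
    master_seed: int = 0,
) -> IntervalPair:
    """Group intervals on one gene's normalized expression."""
    scores = cohort.expression(gene).to_dict()
    kind = f"gene:{gene}"
    return IntervalPair(
        il_interval=_group_interval(
            scores, partition.train_il, kind, "IL",
            method=method, n_boot=n_boot, master_seed=master_seed,
        ),
        nil_interval=_group_interval(
            scores, partition.train_nil, kind, "NIL",
            method=method, n_boot=n_boot, master_seed=master_seed,
        ),
    )


def construct_null_2gene(
    partition: Partition,
    gene_pair: tuple[str, str],
    cohort: Cohort,
    *,
    method: str = "bootstrap-median",
    n_boot: int = DEFAULT_N_BOOT,
    master_seed: int = 0,
) -> RectanglePair:
    """Per-group rectangles as products of the two genes' intervals.

    Reuses the per-gene intervals of the single-gene construction (same
    scores, same seeds), so a two-gene rectangle pair separates exactly when
    at least one of its genes' interval pairs separates.
    """
    g1, g2 = gene_pair
    if g1 == g2:
        raise ValueError("two-gene null classifier needs two distinct genes")
    iv1 = construct_null_1gene(
        partition, g1, cohort, method=method, n_boot=n_boot, master_seed=master_seed
    )
    iv2 = construct_null_1gene(
        partition, g2, cohort, method=method, n_boot=n_boot, master_seed=master_seed
    )
    return RectanglePair(
        il_region=(iv1.il_interval, iv2.il_interval),
        nil_region=(iv1.nil_interval, iv2.nil_interval),
    )


def _in_interval(x: float, interval: tuple[float, float]) -> bool:
    return interval[0] <= x <= interval[1]


def classify_sample(score, regions: IntervalPair | RectanglePair) -> str:
    """Call one test sample IL, NIL or no-call by closed-region membership.

    Scores falling in neither region are no-calls, whether between the
    regions or outside both; disjointness precludes membership in both.
    """
    if not regions.separated:
        raise ClassifierUsageError("classifier was not constructed (regions overlap)")
    if isinstance(regions, IntervalPair):
        in_il = _in_interval(score, regions.il_interval)
        in_nil = _in_interval(score, regions.nil_interval)
    else:
        x, y = score
        in_il = _in_interval(x, regions.il_region[0]) and _in_interval(y, regions.il_region[1])
        in_nil = _in_interval(x, regions.nil_region[0]) and _in_interval(y, regions.nil_region[1])
    if in_il:
        return "IL"
    if in_nil:
        return "NIL"
    return "no-call"


def evaluate(calls: Mapping[str, str], truth: Mapping[str, str]) -> tuple[float, float]:
    """Precision and recall of per-test-sample calls.

    precision = correctly classified / classified (0 when nothing was
    classified); recall = classified / total test samples, so no-calls count
    against recall only.
    """
    total = len(calls)
    classified = sum(1 for c in calls.values() if c != "no-call")
    correct = sum(1 for sid, c in calls.items() if c != "no-call" and c == truth[sid])
    precision = correct / classified if classified else 0.0
    recall = classified / total if total else 0.0
    return precision, recall


def _fscore(precision: float, recall: float) -> float:
    s = precision + recall
    return 2.0 * precision * recall / s if s > 0 else 0.0


@dataclass(frozen=True)
class ClassifierOutcome:
    """Per-(partition, configuration) record of construction and performance."""

    partition_id: int
    kind: str  # model | null-1gene | null-2gene
    predictor: str
    constructed: bool
    calls: dict = field(default_factory=dict)
    precision: float = float("nan")
    recall: float = float("nan")

    @property
    def f_score(self) -> float:
        if not self.constructed:
            return float("nan")
        return _fscore(self.precision, self.recall)


# ---------------------------------------------------------------------------
# The exhaustive sweep (vectorized over partitions)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepConfig:
    """Knobs of the exhaustive sweep.

    ``grid`` controls the basin-probability estimator used for model scores
    (101 cells per axis by default: probabilities enter only through interval
    comparisons, so sub-0.01 area precision buys nothing).  ``subsample``
    evaluates a seeded random subset of partitions instead of all of them,
    for larger synthetic cohorts; CSR is then relative to the subsample.
    """

    ci_method: str = "bootstrap-median"
    n_boot: int = DEFAULT_N_BOOT
    master_seed: int = 0
    grid: BasinGridSpec = field(default_factory=lambda: BasinGridSpec(resolution=101))
    subsample: int | None = None


@dataclass
class SweepResult:
    """Outcome table plus per-configuration aggregates.

    ``outcomes`` is a long table (partition_id, kind, predictor, constructed,
    precision, recall, f_score); the summaries carry avg_f_score over
    constructed instances and CSR per configuration.
    """

    outcomes: pd.DataFrame
    model_summary: pd.DataFrame
    null_summary: pd.DataFrame
    n_partitions: int
    probabilities: pd.DataFrame  # sample x predictor labor probabilities


def sample_probabilities(
    cohort: Cohort, grid: BasinGridSpec | None = None
) -> pd.DataFrame:
    """Labor probability of every sample under each of the six predictors.

    At most 108 distinct (b, i) pairs arise from an 18-sample cohort; the
    basin cache makes repeated evaluation free.  Near-degenerate parameters
    (i just below k) converge slowly; on a precision failure the horizon is
    extended and the evaluation retried.
    """
    from dataclasses import replace as _replace

    from .labor_probability import PrecisionError

    def value(p) -> float:
        spec = grid
        for _ in range(4):
            try:
                return basin_probability(p, spec).value
            except PrecisionError:
                spec = _replace(spec or BasinGridSpec(), t_max=(spec or BasinGridSpec()).t_max * 4)
        return basin_probability(p, spec).value

    cols = {}
    for predictor in all_predictors():
        params = parameterize(cohort, predictor)
        cols[predictor.name] = {sid: value(p) for sid, p in params.items()}
    return pd.DataFrame(cols).loc[cohort.sample_ids]


def _subset_matrix(ids: list[str], size: int) -> np.ndarray:
    return np.array(list(combinations(range(len(ids)), size)), dtype=np.intp)


def _bootstrap_intervals(
    scores: np.ndarray,
    subset_rows: np.ndarray,
    member_ids: list[str],
    needed: np.ndarray,
    kind: str,
    group: str,
    config: SweepConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(lo, hi) arrays over training subsets, NaN where not needed."""
    n_sub = subset_rows.shape[0]
    lo = np.full(n_sub, np.nan)
    hi = np.full(n_sub, np.nan)
    for s in needed:
        row = subset_rows[s]
        subset_ids = tuple(member_ids[j] for j in row)
        lo[s], hi[s] = nonparametric_ci(
            scores[row],
            method=config.ci_method,
            n_boot=config.n_boot,
            seed=ci_seed(config.master_seed, kind, group, subset_ids),
        )
    return lo, hi


def sweep(cohort: Cohort, config: SweepConfig | None = None) -> SweepResult:
    """Evaluate all 21 classifier configurations over all (or a seeded
    subsample of) training partitions.

    Per partition: 6 model classifiers, 5 single-gene nulls and 10 two-gene
    nulls (21 configurations; 370,440 outcomes for the 18-sample cohort).
    Construction failures are recorded, never raised.  Fully deterministic
    under ``config.master_seed``.
    """
    config = config or SweepConfig()
    if not cohort.normalized:
        raise CohortShapeError("sweep requires a normalized cohort")

    il = cohort.ids_in_group("IL")
    nil = cohort.ids_in_group("NIL")
    if len(il) < 2 or len(nil) < 2:
        raise CohortShapeError(
            f"need at least 2 samples per group, got {len(il)} IL / {len(nil)} NIL"
        )
    samples = il + nil
    n_il = len(il)
    sample_pos = {sid: j for j, sid in enumerate(samples)}
    is_il = np.zeros(len(samples), dtype=bool)
    is_il[:n_il] = True

    A = _subset_matrix(il, _train_size(n_il))          # IL training subsets
    B = _subset_matrix(nil, _train_size(len(nil)))     # NIL training subsets
    n_a, n_b = A.shape[0], B.shape[0]
    n_total_partitions = n_a * n_b

    if config.subsample is not None and config.subsample < n_total_partitions:
        rng = np.random.default_rng(
            ci_seed(config.master_seed, "subsample", "partitions", ())
        )
        pids = np.sort(
            rng.choice(n_total_partitions, size=config.subsample, replace=False)
        )
    else:
        pids = np.arange(n_total_partitions)
    a_idx = pids // n_b
    b_idx = pids % n_b
    needed_a = np.unique(a_idx)
    needed_b = np.unique(b_idx)

    # training-membership masks per subset (over the full sample axis)
    il_mask = np.zeros((n_a, len(samples)), dtype=bool)
    for s in needed_a:
        il_mask[s, A[s]] = True
    nil_mask = np.zeros((n_b, len(samples)), dtype=bool)
    for s in needed_b:
        nil_mask[s, B[s] + n_il] = True
    test_mask = ~(il_mask[a_idx] | nil_mask[b_idx])  # (P, S)
    n_test = test_mask.sum(axis=1)

    # score vectors: six predictor probability profiles + five gene profiles
    probabilities = sample_probabilities(cohort, config.grid)
    score_kinds: dict[str, np.ndarray] = {}
    for predictor in all_predictors():
        score_kinds[f"model:{predictor.name}"] = probabilities[predictor.name].loc[
            samples
        ].to_numpy()
    for gene in SURROGATE_GENES:
        score_kinds[f"gene:{gene}"] = cohort.expression(gene).loc[samples].to_numpy()

    # group intervals per (kind, training subset)
    intervals: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for kind, scores in score_kinds.items():
        intervals[(kind, "IL")] = _bootstrap_intervals(
            scores[:n_il], A, il, needed_a, kind, "IL", config
        )
        intervals[(kind, "NIL")] = _bootstrap_intervals(
            scores[n_il:], B, nil, needed_b, kind, "NIL", config
        )

    def axis_state(kind: str):
        """Per-partition separation flag and per-sample membership masks."""
        scores = score_kinds[kind]
        lo_il, hi_il = intervals[(kind, "IL")]
        lo_nil, hi_nil = intervals[(kind, "NIL")]
        sep = (hi_il[a_idx] < lo_nil[b_idx]) | (hi_nil[b_idx] < lo_il[a_idx])
        in_il = (scores >= lo_il[a_idx, None]) & (scores <= hi_il[a_idx, None])
        in_nil = (scores >= lo_nil[b_idx, None]) & (scores <= hi_nil[b_idx, None])
        return sep, in_il, in_nil

    axis_cache = {kind: axis_state(kind) for kind in score_kinds}

    records = []

    def emit(kind_label: str, name: str, sep, in_il, in_nil):
        called_il = in_il & test_mask
        called_nil = in_nil & test_mask
        classified = (called_il | called_nil).sum(axis=1)
        correct = (called_il & is_il).sum(axis=1) + (called_nil & ~is_il).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            precision = np.where(classified > 0, correct / np.maximum(classified, 1), 0.0)
            recall = classified / n_test
        precision = np.where(sep, precision, np.nan)
        recall = np.where(sep, recall, np.nan)
        s = precision + recall
        f = np.where(sep & (s > 0), 2.0 * precision * recall / np.where(s > 0, s, 1.0), np.where(sep, 0.0, np.nan))
        records.append(
            pd.DataFrame(
                {
                    "partition_id": pids,
                    "kind": kind_label,
                    "predictor": name,
                    "constructed": sep,
                    "precision": precision,
                    "recall": recall,
                    "f_score": f,
                }
            )
        )

    for predictor in all_predictors():
        sep, in_il, in_nil = axis_cache[f"model:{predictor.name}"]
        emit("model", predictor.name, sep, in_il, in_nil)
    for gene in SURROGATE_GENES:
        sep, in_il, in_nil = axis_cache[f"gene:{gene}"]
        emit("null-1gene", gene, sep, in_il, in_nil)
    for g1, g2 in combinations(SURROGATE_GENES, 2):
        sep1, il1, nil1 = axis_cache[f"gene:{g1}"]
        sep2, il2, nil2 = axis_cache[f"gene:{g2}"]
        emit("null-2gene", f"{g1}-{g2}", sep1 | sep2, il1 & il2, nil1 & nil2)

    outcomes = pd.concat(records, ignore_index=True)

    def summarize(frame: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (kind, name), grp in frame.groupby(["kind", "predictor"], sort=False):
            constructed = grp["constructed"]
            rows.append(
                {
                    "kind": kind,
                    "predictor": name,
                    "avg_f_score": grp.loc[constructed, "f_score"].mean(),
                    "csr": constructed.mean(),
                }
            )
        return pd.DataFrame(rows)

    model_summary = summarize(outcomes[outcomes["kind"] == "model"])
    null_summary = summarize(outcomes[outcomes["kind"] != "model"])
    return SweepResult(
        outcomes=outcomes,
        model_summary=model_summary,
        null_summary=null_summary,
        n_partitions=len(pids),
        probabilities=probabilities,
    )
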
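"""The core experiment: rearranging per-gesture sample counts in a
constant-size training set and recording recognition rates.

For each step of an assignment schedule, the count of the gesture of
interest rises while the other two gestures' counts shrink so that the
training-set total stays constant (52 in the reference protocol). Training
samples are drawn without replacement from a per-gesture candidate pool (the
70% split); the test set (the remaining 30%) is fixed for the whole sweep.
Mean and SD over repeated training-set resamples are reported per step,
together with a uniform-assignment baseline (17 per gesture, total 51).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier import GAConfig, SVMParams, evaluate, ga_optimize, train

#: interest-gesture training counts of the reference 52-sample schedule
REFERENCE_INTEREST_COUNTS = (6, 10, 16, 20, 26, 30, 36, 42)
REFERENCE_TOTAL = 52
REFERENCE_UNIFORM_PER_GESTURE = 17


@dataclass(frozen=True)
class AssignmentSchedule:
    """Ordered per-gesture training counts at constant total.

    ``gestures`` lists the class names with the gesture of interest first;
    ``steps[k]`` gives the counts in the same order.
    """

    gestures: tuple[str, ...]
    steps: tuple[tuple[int, ...], ...]
    total: int

    def __post_init__(self):
        if len(self.gestures) < 2:
            raise ValueError("schedule needs at least 2 gestures")
        interest = []
        for step in self.steps:
            if len(step) != len(self.gestures):
                raise ValueError("each step needs one count per gesture")
            if sum(step) != self.total:
                raise ValueError(
                    f"step {step} sums to {sum(step)}, expected {self.total}")
            if any(c < 1 for c in step):
                raise ValueError("all counts must be >= 1")
            interest.append(step[0])
        if any(b <= a for a, b in zip(interest, interest[1:])):
            raise ValueError("interest counts must be strictly increasing")

    @property
    def gesture_of_interest(self) -> str:
        return self.gestures[0]

    def counts_dict(self, step_index: int) -> dict[str, int]:
        return dict(zip(self.gestures, self.steps[step_index]))


def default_schedule(gestures: tuple[str, str, str] | list[str],
                     total: int = REFERENCE_TOTAL) -> AssignmentSchedule:
    """The reference 8-step schedule (or a proportional analogue).

    For ``total=52`` the interest counts are (6, 10, 16, 20, 26, 30, 36, 42)
    and the two other gestures share the remainder equally. Other totals use
    the same interest fractions, rounded, with the remainder split as evenly
    as integers allow.
    """
    gestures = tuple(gestures)
    if len(gestures) != 3:
        raise ValueError("the reference schedule is for 3 gestures")
    if total < 3:
        raise ValueError("total must admit at least 1 sample per gesture")
    if total == REFERENCE_TOTAL:
        interest = REFERENCE_INTEREST_COUNTS
    else:
        fracs = [c / REFERENCE_TOTAL for c in REFERENCE_INTEREST_COUNTS]
        interest = []
        for f in fracs:
            k = int(round(f * total))
            k = max(1, min(k, total - 2))
            if not interest or k > interest[-1]:
                interest.append(k)
        interest = tuple(interest)
    steps = []
    for k in interest:
        rest = total - k
        steps.append((k, rest // 2, rest - rest // 2))
    return AssignmentSchedule(gestures=gestures, steps=tuple(steps), total=total)


def uniform_assignment(per_gesture: int = REFERENCE_UNIFORM_PER_GESTURE,
                       n_gestures: int = 3) -> tuple[int, ...]:
    """Equal per-gesture counts (the conventional baseline, 17 x 3 = 51)."""
    if per_gesture < 1 or n_gestures < 1:
        raise ValueError("counts must be >= 1")
    return (per_gesture,) * n_gestures


@dataclass(frozen=True)
class SplitSpec:
    """70/30 candidate/test split sizes per gesture."""

    candidate_per_gesture: int = 42
    test_per_gesture: int = 18
    seed: int = 0

    def __post_init__(self):
        if self.candidate_per_gesture < 1 or self.test_per_gesture < 1:
            raise ValueError("split sizes must be >= 1")


def split_candidates(features: pd.DataFrame,
                     spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded per-gesture split into a candidate pool and a fixed test set."""
    expected = spec.candidate_per_gesture + spec.test_per_gesture
    tallies = features.groupby("gesture", sort=True)["trial_id"].count()
    bad = {g: int(n) for g, n in tallies.items() if n != expected}
    if bad:
        raise ValueError(
            f"expected {expected} trials per gesture, got mismatches: {bad}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    pool_idx, test_idx = [], []
    for gesture in tallies.index:
        idx = features.index[features["gesture"] == gesture].to_numpy()
        perm = rng.permutation(idx)
        pool_idx.extend(perm[:spec.candidate_per_gesture])
        test_idx.extend(perm[spec.candidate_per_gesture:])
    pool = features.loc[pool_idx].reset_index(drop=True)
    test = features.loc[test_idx].reset_index(drop=True)
    return pool, test


def build_training_set(pool: pd.DataFrame, counts: dict[str, int],
                       rng: np.random.Generator) -> pd.DataFrame:
    """Sample ``counts[g]`` pool trials per gesture without replacement."""
    parts = []
    for gesture, k in counts.items():
        idx = pool.index[pool["gesture"] == gesture].to_numpy()
        if k > idx.size:
            raise ValueError(
                f"requested {k} training samples of '{gesture}' but the pool "
                f"holds only {idx.size}")
        take = rng.choice(idx, size=k, replace=False)
        parts.append(pool.loc[take])
    return pd.concat(parts, ignore_index=True)


@dataclass
class StepResult:
    counts: dict[str, int]
    recall_mean: dict[str, float]
    recall_sd: dict[str, float]
    overall_mean: float
    overall_sd: float
    params: list[SVMParams] = field(default_factory=list)


@dataclass
class SweepResult:
    gesture_of_interest: str
    gestures: tuple[str, ...]
    per_step: list[StepResult]
    uniform_baseline: StepResult
    repeats: int


def _run_assignment(pool, test, counts, ga_config, repeats, seed_seq,
                    fixed_params: SVMParams | None) -> StepResult:
    gestures = list(counts)
    recalls = {g: [] for g in gestures}
    overalls, used_params = [], []
    children = seed_seq.spawn(repeats)
    for r in range(repeats):
        child = children[r]
        rng = np.random.default_rng(child)
        training = build_training_set(pool, counts, rng)
        if fixed_params is None:
            ga_seed = int(child.generate_state(1)[0] % (2 ** 31))
            params, _ = ga_optimize(training, replace(ga_config, seed=ga_seed))
        else:
            params = fixed_params
        model = train(params, training)
        ev = evaluate(model, test)
        for g in gestures:
            recalls[g].append(ev.per_class_recall.get(g, 0.0))
        overalls.append(ev.overall_accuracy)
        used_params.append(params)
    return StepResult(
        counts=dict(counts),
        recall_mean={g: float(np.mean(v)) for g, v in recalls.items()},
        recall_sd={g: float(np.std(v)) for g, v in recalls.items()},
        overall_mean=float(np.mean(overalls)),
        overall_sd=float(np.std(overalls)),
        params=used_params,
    )


def run_sweep(
    features: pd.DataFrame,
    schedule: AssignmentSchedule,
    split_spec: SplitSpec,
    ga_config: GAConfig = GAConfig(),
    repeats: int = 10,
    master_seed: int = 0,
    retune: str = "step",
    uniform_per_gesture: int | None = None,
) -> SweepResult:
    """Run the full proportion sweep plus the uniform baseline.

    ``retune='step'`` re-runs the GA for every training resample (the
    conservative reading of the protocol); ``retune='global'`` tunes once on
    a uniform training set drawn from the pool and reuses those parameters
    everywhere (much faster, appropriate for scaled-down runs).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if retune not in ("step", "global"):
        raise ValueError("retune must be 'step' or 'global'")
    pool, test = split_candidates(features, split_spec)
    ss = np.random.SeedSequence(master_seed)
    n_assign = len(schedule.steps) + 1
    children = ss.spawn(n_assign + 1)

    fixed_params: SVMParams | None = None
    if retune == "global":
        rng = np.random.default_rng(children[n_assign])
        per = uniform_per_gesture
        if per is None:
            per = schedule.total // len(schedule.gestures)
        counts = dict(zip(schedule.gestures,
                          uniform_assignment(per, len(schedule.gestures))))
        tune_set = build_training_set(pool, counts, rng)
        ga_seed = int(children[n_assign].generate_state(2)[1] % (2 ** 31))
        fixed_params, _ = ga_optimize(tune_set, replace(ga_config, seed=ga_seed))

    per_step = []
    for i in range(len(schedule.steps)):
        per_step.append(_run_assignment(
            pool, test, schedule.counts_dict(i), ga_config, repeats,
            children[i], fixed_params))

    per = uniform_per_gesture
    if per is None:
        per = (REFERENCE_UNIFORM_PER_GESTURE
               if schedule.total == REFERENCE_TOTAL
               else schedule.total // len(schedule.gestures))
    baseline_counts = dict(zip(schedule.gestures,
                               uniform_assignment(per, len(schedule.gestures))))
    baseline = _run_assignment(pool, test, baseline_counts, ga_config,
                               repeats, children[len(schedule.steps)],
                               fixed_params)
    return SweepResult(
        gesture_of_interest=schedule.gesture_of_interest,
        gestures=schedule.gestures,
        per_step=per_step,
        uniform_baseline=baseline,
        repeats=repeats,
    )


def find_peak(result: SweepResult) -> tuple[int, dict[str, int]]:
    """Schedule step with the highest mean overall accuracy.

    Ties break toward the most uniform counts (smallest max - min), then the
    lowest step index.
    """
    if not result.per_step:
        raise ValueError("empty sweep result")

    def key(i: int):
        step = result.per_step[i]
        counts = list(step.counts.values())
        return (-step.overall_mean, max(counts) - min(counts), i)

    best = min(range(len(result.per_step)), key=key)
    return best, dict(result.per_step[best].counts)


def sweep_frame(result: SweepResult) -> pd.DataFrame:
    """Tidy per-step table (baseline last, step = 'uniform')."""
    rows = []
    for i, step in enumerate([*result.per_step, result.uniform_baseline]):
        label = str(i + 1) if i < len(result.per_step) else "uniform"
        row = {"step": label}
        for g in result.gestures:
            row[f"count_{g}"] = step.counts[g]
        for g in result.gestures:
            row[f"recall_mean_{g}"] = step.recall_mean[g]
            row[f"recall_sd_{g}"] = step.recall_sd[g]
        row["overall_mean"] = step.overall_mean
        row["overall_sd"] = step.overall_sd
        rows.append(row)
    return pd.DataFrame(rows)
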
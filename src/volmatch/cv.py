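"""Nested k x l cross-validation harness (default 5 x 5).

The cohort is split uniformly at random into ``k`` near-equal outer folds;
each outer round holds one fold back for testing and splits the remaining
subjects into ``l`` near-equal inner folds, of which one serves as the
validation set for checkpointing and learning-rate control while the other
``l - 1`` (64% of the data at 5 x 5) form the actual training set.  Every
(outer, inner) pair is one training run — 25 runs per plan — evaluated on
its outer test fold using the minimum-validation-loss checkpoint; the mean
over runs is reported.  A bookkeeping audit verifies that no test subject
ever influenced parameter updates or schedule decisions of its run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import EvalReport, roc_auc
from .models import BraiNN, BraiNNSpec, VoxelLogit
from .training import ScheduleState, step_schedule  # re-exported surface

__all__ = [
    "SplitPlan", "CVRun", "CVResults", "make_nested_splits", "run_nested_cv",
    "LeakageError", "ScheduleState", "step_schedule", "SCENARIO_EPOCHS",
]

#: Training epochs per scenario, per model kind.
SCENARIO_EPOCHS = {
    "complete": {"logreg": 30, "brainn": 100},
    "reduced": {"logreg": 30, "brainn": 100},
    "matched": {"logreg": 30, "brainn": 200},
    "roi": {"logreg": 60, "brainn": 200},
}


class LeakageError(RuntimeError):
    """A test subject leaked into training or schedule decisions."""


@dataclass(frozen=True)
class FoldRun:
    outer: int
    inner: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class SplitPlan:
    """Nested outer x inner fold assignment of subject ids."""

    k: int
    l: int
    seed: int
    outer_folds: list[list[str]]
    runs: list[FoldRun]

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def _partition(ids: np.ndarray, parts: int) -> list[list[str]]:
    # np.array_split gives sizes differing by at most one (remainder spread
    # over the leading folds)
    return [list(chunk) for chunk in np.array_split(ids, parts)]


def make_nested_splits(ids, k: int = 5, l: int = 5,
                       seed: int = 0) -> SplitPlan:
    """Build the nested fold plan: ``k * l`` train/validation/test runs."""
    ids = np.asarray(list(ids))
    if len(ids) < k * l:
        raise ValueError(f"need at least k*l={k * l} subjects, got {len(ids)}")
    if len(set(ids.tolist())) != len(ids):
        raise ValueError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    outer_folds = _partition(rng.permutation(ids), k)
    runs: list[FoldRun] = []
    for o in range(k):
        rest = np.concatenate([np.asarray(f) for j, f in enumerate(outer_folds)
                               if j != o])
        inner_folds = _partition(rng.permutation(rest), l)
        for i in range(l):
            train = [s for j, f in enumerate(inner_folds) if j != i for s in f]
            runs.append(FoldRun(outer=o, inner=i,
                                train_ids=tuple(train),
                                val_ids=tuple(inner_folds[i]),
                                test_ids=tuple(outer_folds[o])))
    return SplitPlan(k=k, l=l, seed=seed, outer_folds=outer_folds, runs=runs)


@dataclass
class CVRun:
    """One training run's evaluation on its outer test fold."""

    outer: int
    inner: int
    test_ids: tuple[str, ...]
    report: EvalReport
    val_loss: list[float]
    lr_history: list[float]
    results: object | None = None

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def auc(self) -> float:
        return self.report.auc


@dataclass
class CVResults:
    """Aggregate of all nested-CV runs."""

    model_kind: str
    scenario: str
    plan: SplitPlan
    runs: list[CVRun]
    subject_scores: dict[str, list[float]] = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.runs]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.runs]))

    @property
    def models(self) -> list:
        return [r.results for r in self.runs]

    def mean_subject_scores(self) -> dict[str, float]:
        return {s: float(np.mean(v)) for s, v in self.subject_scores.items()}

    def summary(self) -> str:
        accs = [r.accuracy for r in self.runs]
        aucs = [r.auc for r in self.runs]
        return "\n".join([
            f"Nested {self.plan.k}x{self.plan.l} cross-validation "
            f"({self.model_kind}, scenario '{self.scenario}')",
            f"  runs:          {len(self.runs)}",
            f"  mean accuracy: {100 * np.mean(accs):.2f}% "
            f"(sd {100 * np.std(accs):.2f})",
            f"  mean AUC:      {np.mean(aucs):.3f} (sd {np.std(aucs):.3f})",
        ])


def _run_seed(seed: int, outer: int, inner: int) -> int:
    child = np.random.SeedSequence(entropy=seed, spawn_key=(outer, inner))
    return int(child.generate_state(1)[0] % (2 ** 31))


def run_nested_cv(
    images: np.ndarray,
    labels: np.ndarray,
    ids,
    model_kind: str = "logreg",
    scenario: str = "matched",
    *,
    seed: int = 0,
    k: int = 5,
    l: int = 5,
    plan: SplitPlan | None = None,
    epochs: int | None = None,
    lr: float = 1e-4,
    batch_size: int = 16,
    penalty: float = 0.1,
    spec: BraiNNSpec | None = None,
    keep_models: bool = True,
) -> CVResults:
    """Train and evaluate a classifier under nested cross-validation.

    ``scenario`` selects the per-model epoch count (see
    :data:`SCENARIO_EPOCHS`) unless ``epochs`` overrides it.  Each run's
    RNG derives from ``(seed, outer, inner)`` so runs are independently
    reproducible.
    """
    if model_kind not in ("logreg", "brainn"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    if scenario not in SCENARIO_EPOCHS:
        raise ValueError(f"unknown scenario {scenario!r}")
    ids = list(ids)
    labels = np.asarray(labels)
    pos = {s: i for i, s in enumerate(ids)}
    if plan is None:
        plan = make_nested_splits(ids, k=k, l=l, seed=seed)
    n_epochs = epochs if epochs is not None else SCENARIO_EPOCHS[scenario][model_kind]

    runs: list[CVRun] = []
    subject_scores: dict[str, list[float]] = {s: [] for s in ids}
    for fr in plan.runs:
        touched = set(fr.train_ids) | set(fr.val_ids)
        if touched & set(fr.test_ids):
            raise LeakageError(
                f"run ({fr.outer},{fr.inner}): test ids overlap "
                f"train/validation ids")
        tr = [pos[s] for s in fr.train_ids]
        va = [pos[s] for s in fr.val_ids]
        te = [pos[s] for s in fr.test_ids]
        run_seed = _run_seed(seed, fr.outer, fr.inner)
        if model_kind == "logreg":
            model = VoxelLogit(images[tr], labels[tr], penalty=penalty)
        else:
            model = BraiNN(images[tr], labels[tr], spec=spec, seed=run_seed)
        res = model.fit(epochs=n_epochs, lr=lr, batch_size=batch_size,
                        validation=(images[va], labels[va]), seed=run_seed)
        rec = res.record
        if rec.val_loss and rec.checkpoint_val_loss > min(rec.val_loss) + 1e-12:
            raise LeakageError("checkpoint is not the minimum-validation-loss "
                               "state")  # defensive: protocol violation
        scores = res.predict(images[te])
        report = roc_auc(scores, labels[te])
        for s, z in zip(fr.test_ids, scores):
            subject_scores[s].append(float(z))
        runs.append(CVRun(outer=fr.outer, inner=fr.inner, test_ids=fr.test_ids,
                          report=report, val_loss=list(rec.val_loss),
                          lr_history=list(rec.lr_history),
                          results=res if keep_models else None))
    return CVResults(model_kind=model_kind, scenario=scenario, plan=plan,
                     runs=runs, subject_scores=subject_scores)
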
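"""Repeated-training stability protocol and majority-vote categories.

Stochastic training of a small CNN on a small cohort is seed-sensitive, so
the whole train/validate/test cycle is repeated (default 100 times) with
run i seeded base_seed + i, the test set frozen across runs. The resulting
runs x subjects prediction matrix supports per-run metric aggregation and
a majority-vote confusion category per subject: a subject is assigned to
the confusion cell (TP/TN/FP/FN) it occupies in strictly more than half of
the runs, and left unassigned at an exact tie.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import SplitSpec
from .model import TrainingConfig, build_model, predict, train

CATEGORIES = ("TP", "TN", "FP", "FN")


@dataclass
class RunEnsemble:
    """Per-subject predicted labels across seed-varied runs."""

    predictions: np.ndarray  # (n_runs, n_subjects) of {0,1}
    run_seeds: list
    reference_labels: np.ndarray
    subject_ids: tuple

    def __post_init__(self):
        self.predictions = np.atleast_2d(np.asarray(self.predictions, dtype=int))
        self.reference_labels = np.asarray(self.reference_labels, dtype=int)
        if self.predictions.shape[1] != self.reference_labels.size:
            raise ValueError("one prediction column per test subject required")

    @property
    def n_runs(self) -> int:
        return self.predictions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_runs):
            for j, sid in enumerate(self.subject_ids):
                rows.append(
                    {
                        "run": r,
                        "case_id": sid,
                        "predicted": int(self.predictions[r, j]),
                        "reference": int(self.reference_labels[j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CategoryAssignment:
    """Majority-vote confusion category per subject."""

    categories: dict  # subject id -> {TP, TN, FP, FN, unassigned}
    assignment_threshold: int
    counts: pd.DataFrame  # per-subject counts in each category

    def indicator(self, category: str) -> np.ndarray:
        """Binary membership vector for one category, in subject order."""
        return np.array(
            [1 if c == category else 0 for c in self.categories.values()]
        )


def run_protocol(
    cases,
    split: SplitSpec,
    config: TrainingConfig,
    n_runs: int = 100,
    base_seed: int = 0,
    resplit_per_run: bool = False,
) -> RunEnsemble:
    """Train from scratch n_runs times and predict the hold-out test set.

    Run i uses seed base_seed + i for initialization and shuffling. By
    default only training stochasticity varies; ``resplit_per_run``
    additionally re-draws the train/validation membership (never the test
    set) per run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    by_id = {c.case_id: c for c in cases}
    test_cases = [by_id[i] for i in split.test_ids]
    reference = np.array([c.label for c in test_cases], dtype=int)
    preds = np.zeros((n_runs, len(test_cases)), dtype=int)
    seeds = []
    pool = list(split.train_ids) + list(split.val_ids)
    for i in range(n_runs):
        seed = base_seed + i
        seeds.append(seed)
        cfg = replace(config, seed=seed)
        if resplit_per_run:
            perm = np.random.default_rng([seed, 2]).permutation(len(pool))
            n_train = len(split.train_ids)
            train_ids = [pool[p] for p in perm[:n_train]]
            val_ids = [pool[p] for p in perm[n_train:]]
        else:
            train_ids, val_ids = split.train_ids, split.val_ids
        try:
            model = build_model(cfg)
            model, _ = train(
                model,
                [by_id[j] for j in train_ids],
                [by_id[j] for j in val_ids],
                cfg,
            )
            preds[i] = predict(model, test_cases)
        except Exception as exc:
            raise RuntimeError(f"protocol run {i} failed: {exc}") from exc
    return RunEnsemble(preds, seeds, reference, tuple(split.test_ids))


def run_confusion_cells(ensemble: RunEnsemble) -> np.ndarray:
    """(n_runs, n_subjects) array of confusion-cell names per run."""
    ref = ensemble.reference_labels[None, :]
    pred = ensemble.predictions
    cells = np.where(
        ref == 1,
        np.where(pred == 1, "TP", "FN"),
        np.where(pred == 1, "FP", "TN"),
    )
    return cells


def assign_categories(
    ensemble: RunEnsemble, threshold_count: int | None = None
) -> CategoryAssignment:
    """Majority-vote category per subject (strictly > threshold_count runs).

    The default threshold is half the number of runs, i.e. the ">50 of
    100" rule; a subject hitting the boundary exactly stays unassigned.
    """
    thr = ensemble.n_runs // 2 if threshold_count is None else threshold_count
    cells = run_confusion_cells(ensemble)
    categories = {}
    rows = []
    for j, sid in enumerate(ensemble.subject_ids):
        counts = {c: int((cells[:, j] == c).sum()) for c in CATEGORIES}
        winner = max(counts, key=counts.get)
        categories[sid] = winner if counts[winner] > thr else "unassigned"
        rows.append({"case_id": sid, **counts, "category": categories[sid]})
    return CategoryAssignment(categories, thr, pd.DataFrame(rows))
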
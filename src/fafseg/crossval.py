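"""Grouped rotating cross-validation with a fixed validation set.

The experimental protocol: a validation set of fixed size is chosen once
(and kept identical across folds); the remaining samples are split into
``n_folds`` pairwise-disjoint rotating test sets whose union covers all
non-validation samples; everything else is training data.  Samples are
grouped by subject -- both eyes of one patient are never split across
the training and test side of any fold, and validation subjects never
appear in any train or test set.

With 90 single-eye subjects, 8 folds and 10 validation samples this
reproduces per-fold sizes 70 train / 10 validation / 10 test; with 206
samples from 127 subjects and 22 validation samples, 161 / 22 / 23.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as fio
from .estimator import AttentionUNetSegmenter
from .metrics import evaluate_pair

__all__ = ["FoldPlan", "make_fold_plan", "load_subject_table", "train_fold", "evaluate_fold"]

REQUIRED_COLUMNS = ("sample_id", "subject_id")


def load_subject_table(path) -> pd.DataFrame:
    """Read a subject table CSV (sample_id, subject_id, eye, image, mask_t0[, mask_t12])."""
    table = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    validate_subject_table(table)
    return table


def validate_subject_table(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"subject table is missing required column {col!r}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in subject table: {dup!r}")


@dataclass
class FoldPlan:
    """A complete grouped cross-validation plan."""

    n_folds: int
    validation_ids: list[str]
    test_ids: list[list[str]] = field(default_factory=list)
    train_ids: list[list[str]] = field(default_factory=list)

    def fold(self, k: int) -> tuple[list[str], list[str], list[str]]:
        return self.train_ids[k], self.validation_ids, self.test_ids[k]

    def to_json(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "validation_ids": list(self.validation_ids),
            "test_ids": [list(t) for t in self.test_ids],
            "train_ids": [list(t) for t in self.train_ids],
        }

    def save(self, path) -> None:
        fio.write_json(path, self.to_json())

    @classmethod
    def load(cls, path) -> "FoldPlan":
        with open(path) as fh:
            return cls(**json.load(fh))

    def verify(self, table: pd.DataFrame) -> None:
        """Assert every structural invariant of the plan against its table."""
        all_ids = set(table["sample_id"])
        val = set(self.validation_ids)
        subj = table.set_index("sample_id")["subject_id"]
        covered: set = set()
        for k in range(self.n_folds):
            train, test = set(self.train_ids[k]), set(self.test_ids[k])
            if train & test or train & val or test & val:
                raise AssertionError(f"fold {k}: train/val/test overlap")
            if train | test | val != all_ids:
                raise AssertionError(f"fold {k}: train+val+test does not cover the table")
            if covered & test:
                raise AssertionError(f"fold {k}: test set overlaps an earlier fold")
            covered |= test
            if set(subj[list(train)]) & set(subj[list(test)]):
                raise AssertionError(f"fold {k}: a subject is split across train/test")
            if set(subj[list(train)]) & set(subj[list(val)]):
                raise AssertionError(f"fold {k}: a subject is split across train/validation")
        if covered != all_ids - val:
            raise AssertionError("union of test sets != all non-validation samples")


def _pick_validation(groups: list[tuple[str, list[str]]], n_validation: int,
                     rng: np.random.Generator):
    """Choose whole subjects whose sample counts sum exactly to n_validation."""
    if n_validation == 0:
        return [], groups
    for _ in range(200):
        order = rng.permutation(len(groups))
        chosen, remaining, total = [], [], 0
        for gi in order:
            sid, samples = groups[gi]
            if total + len(samples) <= n_validation:
                chosen.append(groups[gi])
                total += len(samples)
            else:
                remaining.append(groups[gi])
        if total == n_validation:
            return chosen, remaining
    raise ValueError(
        f"could not select whole subjects summing to exactly {n_validation} "
        "validation samples"
    )


def make_fold_plan(
    table: pd.DataFrame,
    n_folds: int = 8,
    n_validation: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Build the grouped rotating fold plan (deterministic for a fixed seed).

    The validation set is chosen once, before folding.  Remaining
    subjects are dealt, largest first, to the fold with the most
    remaining capacity, balancing test-set sizes to within +/-1 sample;
    an irreducible imbalance beyond that raises an error naming the
    subject that cannot be placed.
    """
    validate_subject_table(table)
    rng = np.random.default_rng(seed)
    grouped = [
        (sid, list(sub["sample_id"]))
        for sid, sub in table.groupby("subject_id", sort=True)
    ]
    val_groups, rest = _pick_validation(grouped, n_validation, rng)
    validation_ids = sorted(s for _, samples in val_groups for s in samples)

    n_rest = sum(len(samples) for _, samples in rest)
    if n_rest < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n_rest} samples")
    base, extra = divmod(n_rest, n_folds)
    capacities = [base + (1 if k < extra else 0) for k in range(n_folds)]
    if extra:
        import warnings

        warnings.warn(
            f"{n_rest} non-validation samples are not divisible by {n_folds} folds; "
            "test sets are balanced to within one sample"
        )

    # deal subjects largest-first (random tie order) to the emptiest fold
    order = rng.permutation(len(rest))
    subjects = sorted((rest[i] for i in order), key=lambda g: -len(g[1]))
    fold_test: list[list[str]] = [[] for _ in range(n_folds)]
    remaining = list(capacities)
    for sid, samples in subjects:
        k = int(np.argmax(remaining))
        if len(samples) > remaining[k] and len(samples) > max(remaining):
            raise ValueError(
                f"subject {sid!r} with {len(samples)} samples cannot be placed "
                "without unbalancing fold sizes beyond one sample"
            )
        fold_test[k].extend(samples)
        remaining[k] -= len(samples)

    sizes = [len(t) for t in fold_test]
    if max(sizes) - min(sizes) > 1:
        raise ValueError(
            f"fold test sizes {sizes} differ by more than one sample; "
            "subject grouping prevents a balanced plan"
        )

    rest_ids = {s for _, samples in rest for s in samples}
    test_ids = [sorted(t) for t in fold_test]
    train_ids = [sorted(rest_ids - set(t)) for t in test_ids]
    return FoldPlan(
        n_folds=n_folds,
        validation_ids=validation_ids,
        test_ids=test_ids,
        train_ids=train_ids,
    )


# ---------------------------------------------------------------- training

def _load_stack(table: pd.DataFrame, ids: list[str], label_column: str):
    sub = table.set_index("sample_id").loc[ids]
    images, masks = [], []
    for sid, row in sub.iterrows():
        img, mask = fio.read_sample(row["image"], row[label_column])
        images.append(img)
        masks.append(mask)
    return np.stack(images), np.stack(masks)


def train_fold(
    table: pd.DataFrame,
    plan: FoldPlan,
    fold_index: int,
    estimator: AttentionUNetSegmenter | None = None,
    target_label: str = "t0",
    **estimator_kwargs,
):
    """Train one fold; returns the fitted estimator.

    ``target_label='t0'`` trains baseline segmentation (mask_t0 column);
    ``'t12_registered'`` trains progression prediction against the
    registered Month-12 masks (mask_t12 column), which must be present
    for every training sample.
    """
    if fold_index >= plan.n_folds:
        raise ValueError(f"fold_index {fold_index} out of range (n_folds={plan.n_folds})")
    label_column = {"t0": "mask_t0", "t12_registered": "mask_t12"}.get(target_label)
    if label_column is None:
        raise ValueError(f"unknown target_label {target_label!r}")
    if label_column not in table.columns or table[label_column].isna().any():
        raise ValueError(
            f"target_label={target_label!r} requires a complete {label_column!r} column"
        )
    est = estimator if estimator is not None else AttentionUNetSegmenter(**estimator_kwargs)
    train, val, _ = plan.fold(fold_index)
    X, y = _load_stack(table, train, label_column)
    validation = _load_stack(table, val, label_column) if val else None
    est.fit(X, y, validation_data=validation)
    return est


def evaluate_fold(
    est: AttentionUNetSegmenter,
    table: pd.DataFrame,
    plan: FoldPlan,
    fold_index: int,
    target_label: str = "t0",
) -> pd.DataFrame:
    """Per-image metrics of a fitted estimator on its fold's test set."""
    label_column = {"t0": "mask_t0", "t12_registered": "mask_t12"}[target_label]
    _, _, test = plan.fold(fold_index)
    X, y = _load_stack(table, test, label_column)
    preds = est.predict(X)
    rows = []
    for sid, pred, gt in zip(test, preds, y):
        ms = evaluate_pair(pred, gt)
        rows.append({"sample_id": sid, "fold": fold_index, **ms.as_dict()})
    return pd.DataFrame(rows)
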
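"""Wrapper feature selection and the top-5-of-100 infection calculator.

Two-stage procedure:

1. **Wrapper selection.** Every nonempty gene combination (up to a size cap)
   is scored by stratified 10-fold cross-validation of the classifier network
   itself; combinations whose mean held-out misclassification is below the
   20% error threshold "pass". The genes appearing most often among passing
   combinations — ties broken by the smaller Mann-Whitney group-difference
   P value — are the selected markers.

2. **Ensemble.** For the selected genes, 100 networks are trained, each on an
   independent stratified 70/30 train/test split with its own random
   initialization; the five with the smallest held-out MSE become the
   infection calculator. A sample is classified as infection when the mean of
   the five member probabilities is at least 0.5, and the reported confidence
   is the rounded mean probability assigned to the chosen label (a percent in
   [50, 100]).

Patients missing any gene of a combination are dropped for that combination
only (the ultrafast instrument lacks four of the twelve assays, so
per-combination complete-case handling keeps every usable patient in play).
All randomness — fold assignment, splits, initializations — derives from a
single top-level seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import diagnostics
from .expression import CohortTable
from .mlp import NetworkConfig, TrainedNetwork, predict, train_network


class CrossValidationError(ValueError):
    """Too few complete-case patients for the requested fold count."""


class SelectionError(ValueError):
    """No gene combination passed the error threshold."""


class CombinatorialGuardError(ValueError):
    """Refusing to enumerate 2^G combinations for large G without override."""


class EnsembleError(ValueError):
    """Ensemble training or classification contract violation."""


# --------------------------------------------------------------------------
# Cross-validated combination scoring
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationResult:
    """Cross-validation outcome for one gene combination."""

    genes: tuple[str, ...]
    cv_error: float
    passed: bool
    fold_errors: tuple[float, ...]
    n_patients: int


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition indices into k stratified folds with sizes differing by <= 1.

    Each class is shuffled and dealt round-robin across folds, starting at a
    rotating offset so remainders don't pile onto the first folds.
    """
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[(i + offset) % k].append(int(j))
        offset += len(idx) % k
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate_combination(
    cohort: CohortTable,
    genes: Sequence[str],
    k: int = 10,
    config: NetworkConfig = NetworkConfig(),
    seed: int = 0,
) -> CombinationResult:
    """Score one gene combination by stratified k-fold cross-validation.

    One network is trained per fold on the k-1 remaining folds (scaling fit
    on the training folds only); the fold error is the held-out
    misclassification fraction and ``cv_error`` is their mean. ``passed`` is
    ``cv_error < config.error_threshold``.
    """
    genes = tuple(genes)
    sub = cohort.complete_cases(genes)
    X = sub.matrix(genes)
    y = sub.y()
    n = len(y)
    if n < 2 * k:
        raise CrossValidationError(
            f"{n} complete-case patients for {genes} is fewer than 2k = {2 * k}"
        )
    rng = np.random.default_rng(seed)
    folds = stratified_folds(y, k, rng)
    fold_seeds = rng.integers(0, 2**31, size=k)
    fold_errors = []
    for fold, fseed in zip(folds, fold_seeds):
        train_idx = np.setdiff1d(np.arange(n), fold)
        net = train_network(
            X[train_idx], y[train_idx],
            NetworkConfig(**{**_cfg_dict(config), "seed": int(fseed)}),
            feature_names=genes,
        )
        out = np.atleast_1d(predict(net, X[fold]))
        fold_errors.append(float(np.mean((out >= 0.5) != (y[fold] == 1))))
    cv_error = float(np.mean(fold_errors))
    return CombinationResult(
        genes=genes,
        cv_error=cv_error,
        passed=cv_error < config.error_threshold,
        fold_errors=tuple(fold_errors),
        n_patients=n,
    )


def _cfg_dict(config: NetworkConfig) -> dict:
    return {
        "hidden_sizes": config.hidden_sizes,
        "learning_rate": config.learning_rate,
        "max_epochs": config.max_epochs,
        "error_threshold": config.error_threshold,
        "tol": config.tol,
        "seed": config.seed,
    }


# --------------------------------------------------------------------------
# Wrapper feature selection
# --------------------------------------------------------------------------

#: Refuse full enumeration above this many candidate genes unless overridden.
COMBINATION_HARD_CAP = 15


def run_feature_selection(
    cohort: CohortTable,
    candidate_genes: Sequence[str],
    max_combo_size: int | None = None,
    k: int = 10,
    config: NetworkConfig = NetworkConfig(),
    seed: int = 0,
    allow_large: bool = False,
) -> list[CombinationResult]:
    """Cross-validate every nonempty gene combination up to ``max_combo_size``.

    With the default ``max_combo_size=None`` all ``2^G - 1`` combinations are
    evaluated; G above :data:`COMBINATION_HARD_CAP` raises unless
    ``allow_large`` is set. Results are sorted by ascending cv_error (ties by
    smaller combination, then lexicographic) and the whole sweep is
    deterministic given ``seed``. Combinations with too few complete-case
    patients for k folds are skipped.
    """
    candidate_genes = list(dict.fromkeys(candidate_genes))
    if len(candidate_genes) < 2:
        raise SelectionError("need at least 2 candidate genes")
    if len(candidate_genes) > COMBINATION_HARD_CAP and not allow_large:
        raise CombinatorialGuardError(
            f"{len(candidate_genes)} candidate genes would require "
            f"{2 ** len(candidate_genes) - 1} cross-validations; "
            "pass allow_large=True to proceed"
        )
    max_size = max_combo_size or len(candidate_genes)
    combos = [
        c
        for size in range(1, max_size + 1)
        for c in combinations(candidate_genes, size)
    ]
    seeds = np.random.default_rng(seed).integers(0, 2**31, size=len(combos))
    results = []
    for combo, cseed in zip(combos, seeds):
        try:
            results.append(
                cross_validate_combination(cohort, combo, k=k, config=config, seed=int(cseed))
            )
        except CrossValidationError:
            continue
    results.sort(key=lambda r: (r.cv_error, len(r.genes), r.genes))
    return results


def select_top_genes(
    results: Sequence[CombinationResult],
    cohort: CohortTable,
    top_n: int = 3,
    ranking: str = "frequency",
) -> tuple[str, ...]:
    """Pick the top genes from passing combinations.

    Default ranking counts how often each gene occurs among combinations
    that passed the error threshold and breaks ties by the smaller
    Mann-Whitney group-difference P value on the cohort; ``ranking="pvalue"``
    makes the P value primary and the frequency the tie-break.
    """
    if not results:
        raise SelectionError("no combination results supplied")
    passing = [r for r in results if r.passed]
    if not passing:
        raise SelectionError(
            "no combination passed the error threshold; consider more training "
            "epochs, a higher threshold, or different candidate genes"
        )
    freq: dict[str, int] = {}
    for r in passing:
        for g in r.genes:
            freq[g] = freq.get(g, 0) + 1
    pvals = {g: diagnostics.group_test(cohort, g) for g in freq}
    if ranking == "frequency":
        key = lambda g: (-freq[g], pvals[g], g)
    elif ranking == "pvalue":
        key = lambda g: (pvals[g], -freq[g], g)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    ordered = sorted(freq, key=key)
    return tuple(ordered[:top_n])


# --------------------------------------------------------------------------
# Ensemble training
# --------------------------------------------------------------------------

def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split; per-class train share rounds to nearest."""
    train: list[int] = []
    test: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 2), len(idx) - 1)  # >=2 train, >=1 test per class
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.array(sorted(train)), np.array(sorted(test))


@dataclass
class EnsembleModel:
    """Top-k networks of an independently split and initialized population.

    members are sorted by ascending held-out MSE; member_mses holds those
    MSEs. training_meta records the population size, split fraction and seed
    so any member can be reproduced bit-exactly.
    """

    genes: tuple[str, ...]
    members: list[TrainedNetwork]
    member_mses: list[float]
    training_meta: dict

    def __post_init__(self) -> None:
        if list(self.member_mses) != sorted(self.member_mses):
            raise EnsembleError("members must be sorted by ascending MSE")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "member_mses": list(self.member_mses),
            "training_meta": self.training_meta,
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            genes=tuple(d["genes"]),
            members=[TrainedNetwork.from_dict(m) for m in d["members"]],
            member_mses=[float(m) for m in d["member_mses"]],
            training_meta=d["training_meta"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_ensemble(
    cohort: CohortTable,
    genes: Sequence[str],
    n_networks: int = 100,
    train_fraction: float = 0.7,
    top_k: int = 5,
    config: NetworkConfig = NetworkConfig(),
    seed: int = 0,
) -> EnsembleModel:
    """Train ``n_networks`` networks on independent stratified splits and
    keep the ``top_k`` with the smallest held-out MSE.

    Each member sees a fresh 70/30 (by default) stratified train/test split
    and a fresh weight initialization, both derived from ``seed``; held-out
    MSE ranks the population. Fully reproducible.
    """
    genes = tuple(genes)
    if n_networks < top_k:
        raise EnsembleError(f"n_networks ({n_networks}) < top_k ({top_k})")
    sub = cohort.complete_cases(genes)
    X = sub.matrix(genes)
    y = sub.y()
    if min((y == 1).sum(), (y == 0).sum()) < 3:
        raise EnsembleError("need at least 3 patients per class to split 70/30")
    rng = np.random.default_rng(seed)
    member_seeds = rng.integers(0, 2**31, size=n_networks)
    scored: list[tuple[float, int, TrainedNetwork]] = []
    for i, mseed in enumerate(member_seeds):
        mrng = np.random.default_rng(int(mseed))
        train_idx, test_idx = _stratified_split(y, train_fraction, mrng)
        net = train_network(
            X[train_idx], y[train_idx],
            NetworkConfig(**{**_cfg_dict(config), "seed": int(mrng.integers(2**31))}),
            feature_names=genes,
        )
        out = np.atleast_1d(predict(net, X[test_idx]))
        held_out_mse = float(np.mean((out - y[test_idx]) ** 2))
        scored.append((held_out_mse, i, net))
    scored.sort(key=lambda t: (t[0], t[1]))
    top = scored[:top_k]
    return EnsembleModel(
        genes=genes,
        members=[net for _, _, net in top],
        member_mses=[mse for mse, _, _ in top],
        training_meta={
            "n_trained": n_networks,
            "train_fraction": train_fraction,
            "top_k": top_k,
            "seed": seed,
            "n_patients": len(y),
            "member_indices": [i for _, i, _ in top],
        },
    )


# --------------------------------------------------------------------------
# Classification (the infection calculator)
# --------------------------------------------------------------------------

INFECTION = "infection"
NO_INFECTION = "no infection"


@dataclass(frozen=True)
class ClassificationResult:
    """Calculator verdict: label, percent confidence, raw member outputs."""

    label: str
    confidence: int
    member_outputs: tuple[float, ...]

    @property
    def indicator(self) -> str:
        """Textual red/green indicator for terminal display."""
        return "RED" if self.label == INFECTION else "GREEN"


def aggregate_member_outputs(member_outputs: Sequence[float]) -> ClassificationResult:
    """Combine member probabilities into the calculator verdict.

    Infection iff the mean member probability is >= 0.5; confidence is the
    rounded percent mean probability assigned to the chosen label, hence
    always in [50, 100].
    """
    outputs = tuple(float(p) for p in member_outputs)
    mean_p = float(np.mean(outputs))
    if mean_p >= 0.5:
        label, conf = INFECTION, mean_p
    else:
        label, conf = NO_INFECTION, 1.0 - mean_p
    return ClassificationResult(label, int(round(100 * conf)), outputs)


def classify_sample(model: EnsembleModel, values: Mapping[str, float]) -> ClassificationResult:
    """Classify one patient from a gene -> relative-expression mapping.

    The calculator requires a complete, nonnegative measurement for every
    model gene; anything less is an error rather than a guess.
    """
    missing = [g for g in model.genes if g not in values or values[g] is None]
    if missing:
        raise EnsembleError(f"missing required gene value(s): {missing}")
    x = np.array([float(values[g]) for g in model.genes])
    if np.isnan(x).any():
        raise EnsembleError("gene values must not be NaN")
    if (x < 0).any():
        raise EnsembleError("gene values must be nonnegative")
    outputs = [predict(m, x) for m in model.members]
    return aggregate_member_outputs(outputs)


def member_probabilities(model: EnsembleModel, cohort: CohortTable) -> np.ndarray:
    """Patients x members probability matrix for a complete-case cohort."""
    sub = cohort.complete_cases(model.genes)
    X = sub.matrix(model.genes)
    return np.column_stack([np.atleast_1d(predict(m, X)) for m in model.members])


def classify_cohort(model: EnsembleModel, cohort: CohortTable) -> list[ClassificationResult]:
    """Run the calculator on every complete-case patient of a cohort."""
    probs = member_probabilities(model, cohort)
    return [aggregate_member_outputs(row) for row in probs]
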
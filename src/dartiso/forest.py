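"""Random-forest classification with out-of-bag vote proportions.

The forest follows Breiman's defaults as used in forensic chemometrics:
500 unpruned CART trees, each grown on a bootstrap resample of the same
size as the training set, with floor(sqrt(p)) candidate variables drawn at
each split.  Tree induction is delegated to scikit-learn's
``DecisionTreeClassifier``; the bootstrap resampling is drawn here so that
per-tree bag membership — and therefore out-of-bag (OOB) vote profiles —
is an explicit, inspectable part of the model.

Vote proportions (the fraction of voting trees assigning each isomer) are
the scores fed to the shared acceptance-threshold machinery; variable
importance is the permutation mean decrease in accuracy (MDA) of OOB
argmax classification; robustness to variable removal is probed by a
12-fold cross-validated halving elimination curve; triplicate decision
rules combine the three vote profiles of one card's replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .evaluation import Conclusion, INCONCLUSIVE
from .features import NormalizedTable

logger = logging.getLogger(__name__)


@dataclass
class ForestConfig:
    n_trees: int = 500
    mtry: int | None = None          # None -> floor(sqrt(p)), minimum 1
    seed: int = 0
    min_samples_leaf: int = 1        # unpruned trees
    importance_repeats: int = 5      # permutation passes averaged per variable

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, math.floor(math.sqrt(p)))
        if not 1 <= m <= p:
            raise ValueError(f"mtry must be in [1, {p}], got {m}")
        return m


@dataclass
class IsomerForest:
    """A fitted forest retaining bootstrap membership per tree."""

    config: ForestConfig
    classes: tuple[str, ...]
    variables: tuple[str, ...]
    trees: list[DecisionTreeClassifier] = field(repr=False)
    bootstrap_indices: list[np.ndarray] = field(repr=False)
    X: np.ndarray = field(repr=False)
    y_codes: np.ndarray = field(repr=False)
    sample_ids: tuple[str, ...] = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def oob_masks(self) -> np.ndarray:
        """Boolean (n_trees x n_samples): True where the sample is OOB."""
        n = self.n_samples
        masks = np.empty((len(self.trees), n), dtype=bool)
        for t, idx in enumerate(self.bootstrap_indices):
            masks[t] = np.bincount(idx, minlength=n) == 0
        return masks


def fit_forest(
    values: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    config: ForestConfig | None = None,
) -> IsomerForest:
    """Grow the forest; deterministic given ``config.seed``."""
    config = config or ForestConfig()
    if values.shape[1] == 0:
        raise ValueError("no variables to train on")
    y = pd.Series(np.asarray(labels), index=values.index)
    classes = tuple(sorted(y.unique()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if (y.value_counts() < 2).any():
        raise ValueError("every class needs >= 2 samples")
    X = values.to_numpy(dtype=float)
    codes = np.array([classes.index(c) for c in y])
    n, p = X.shape
    mtry = config.resolved_mtry(p)

    rng = np.random.default_rng(config.seed)
    trees, boots = [], []
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[idx], codes[idx])
        trees.append(tree)
        boots.append(idx)
    return IsomerForest(
        config=config, classes=classes, variables=tuple(values.columns),
        trees=trees, bootstrap_indices=boots, X=X, y_codes=codes,
        sample_ids=tuple(str(i) for i in values.index),
    )


def _tally(forest: IsomerForest, X: np.ndarray, masks: np.ndarray | None) -> np.ndarray:
    """Vote counts (n x K); ``masks`` restricts each tree to its OOB rows."""
    n = X.shape[0]
    K = len(forest.classes)
    votes = np.zeros((n, K))
    all_rows = np.ones(n, dtype=bool)
    for t, tree in enumerate(forest.trees):
        rows = masks[t] if masks is not None else all_rows
        if not rows.any():
            continue
        pred = tree.predict(X[rows])
        np.add.at(votes, (np.where(rows)[0], pred), 1.0)
    return votes


def _profiles_from_votes(
    forest: IsomerForest, votes: np.ndarray, index, oob: bool
) -> pd.DataFrame:
    n_voting = votes.sum(axis=1)
    none = n_voting == 0
    if none.any():
        logger.warning("%d samples were in every bootstrap; no OOB profile", int(none.sum()))
    safe = np.where(none, 1.0, n_voting)
    props = votes / safe[:, None]
    out = pd.DataFrame(props, index=index, columns=list(forest.classes))
    out["n_voting_trees"] = n_voting.astype(int)
    out["oob"] = oob
    return out


def oob_vote_profiles(forest: IsomerForest) -> pd.DataFrame:
    """Per training sample, the vote proportions over trees whose bootstrap
    excluded the sample."""
    masks = forest.oob_masks()
    votes = _tally(forest, forest.X, masks)
    return _profiles_from_votes(forest, votes, pd.Index(forest.sample_ids, name="sample_id"), True)


def predict_vote_profiles(forest: IsomerForest, values: pd.DataFrame) -> pd.DataFrame:
    """Vote proportions for new samples; all trees vote."""
    missing = [c for c in forest.variables if c not in values.columns]
    if missing:
        raise KeyError(f"table is missing model variables: {missing}")
    X = values[list(forest.variables)].to_numpy(dtype=float)
    votes = _tally(forest, X, None)
    return _profiles_from_votes(forest, votes, values.index, False)


def _argmax_accuracy(forest: IsomerForest, votes: np.ndarray) -> float:
    """Plain argmax OOB accuracy (ties resolved to the first class)."""
    voting = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    return float((pred[voting] == forest.y_codes[voting]).mean())


def oob_error(forest: IsomerForest) -> float:
    """Plain argmax out-of-bag error rate."""
    votes = _tally(forest, forest.X, forest.oob_masks())
    return 1.0 - _argmax_accuracy(forest, votes)


def _oob_votes_with_column(
    forest: IsomerForest, masks: np.ndarray, var_idx: int, perm: np.ndarray
) -> np.ndarray:
    Xp = forest.X.copy()
    Xp[:, var_idx] = Xp[perm, var_idx]
    return _tally(forest, Xp, masks)


def permutation_importance(
    forest: IsomerForest,
    seed: int | None = None,
    n_repeats: int | None = None,
) -> pd.DataFrame:
    """Mean decrease in accuracy (MDA) per variable.

    Each variable's values are shuffled among samples, the OOB samples are
    re-classified with plain argmax conclusions, and the drop from the
    baseline OOB accuracy is averaged over ``n_repeats`` shuffles.  The
    identity permutation gives an MDA of exactly 0.
    """
    n_repeats = n_repeats if n_repeats is not None else forest.config.importance_repeats
    rng = np.random.default_rng(forest.config.seed + 1 if seed is None else seed)
    masks = forest.oob_masks()
    baseline = _argmax_accuracy(forest, _tally(forest, forest.X, masks))
    n = forest.n_samples
    mda = np.zeros(len(forest.variables))
    for j in range(len(forest.variables)):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            votes = _oob_votes_with_column(forest, masks, j, perm)
            drops.append(baseline - _argmax_accuracy(forest, votes))
        mda[j] = float(np.mean(drops))
    out = pd.DataFrame({"mda": mda}, index=pd.Index(forest.variables, name="variable"))
    out["rank"] = out["mda"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank")


def elimination_curve(
    values: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    folds: int = 12,
    config: ForestConfig | None = None,
    seed: int = 0,
    rerank: bool = True,
) -> pd.DataFrame:
    """Cross-validated error while halving away the least important variables.

    At each step a stratified ``folds``-fold cross-validated error is
    recorded for the current variable set, importance is ranked (re-ranked
    at each step by default; set ``rerank=False`` to reuse the initial
    ranking), and only the top ``ceil(p/2)`` variables are kept, down to a
    single variable.
    """
    config = config or ForestConfig()
    y = pd.Series(np.asarray(labels), index=values.index)
    if folds > len(values):
        raise ValueError(f"folds={folds} exceeds the {len(values)} samples")
    current = list(values.columns)
    initial_rank: list[str] | None = None
    rows = []
    step = 0
    while True:
        sub = values[current]
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + step)
        errors = []
        for tr, te in skf.split(sub, y):
            fcfg = ForestConfig(
                n_trees=config.n_trees, mtry=None, seed=seed + step,
                min_samples_leaf=config.min_samples_leaf,
                importance_repeats=config.importance_repeats,
            )
            f = fit_forest(sub.iloc[tr], y.iloc[tr], fcfg)
            profiles = predict_vote_profiles(f, sub.iloc[te])
            pred = profiles[list(f.classes)].to_numpy().argmax(axis=1)
            truth = np.array([f.classes.index(c) for c in y.iloc[te]])
            errors.append(float((pred != truth).mean()))
        rows.append({"n_variables": len(current), "cv_error": float(np.mean(errors))})
        if len(current) == 1:
            break
        if rerank or initial_rank is None:
            fcfg = ForestConfig(n_trees=config.n_trees, seed=seed + step,
                                importance_repeats=max(1, config.importance_repeats // 2))
            full = fit_forest(sub, y, fcfg)
            imp = permutation_importance(full, seed=seed + 1000 + step)
            ranking = list(imp.index)                 # best first
            if initial_rank is None:
                initial_rank = ranking
        if rerank:
            order = ranking
        else:
            order = [v for v in initial_rank if v in current]
        keep = math.ceil(len(current) / 2)
        current = [v for v in order[:keep]]
        step += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# triplicate decision rules

TriplicateRule = Literal["all_match", "majority", "highest"]


def triplicate_conclusion(
    profiles: pd.DataFrame,
    rule: TriplicateRule,
    threshold: float,
    id: str = "",
) -> Conclusion:
    """One conclusion per card triplicate from three vote profiles.

    * ``all_match`` — all three argmax classes must agree; the mean of the
      three top proportions is compared to the threshold.
    * ``majority`` — at least two must agree; the mean proportion of the
      agreeing samples is compared to the threshold.
    * ``highest`` — only the sample with the single highest proportion
      speaks; its proportion is compared to the threshold.
    """
    if len(profiles) != 3:
        raise ValueError(f"a triplicate needs exactly 3 profiles, got {len(profiles)}")
    classes = [c for c in profiles.columns if c not in ("n_voting_trees", "oob")]
    P = profiles[classes].to_numpy(dtype=float)
    tops = P.max(axis=1)
    # an argmax tie within one profile is treated as no clear assignment
    ties = (P == tops[:, None]).sum(axis=1) > 1
    assigns = np.where(ties, -1, P.argmax(axis=1))

    if rule == "all_match":
        if len(set(assigns)) == 1 and assigns[0] != -1:
            cls, score = classes[assigns[0]], float(tops.mean())
        else:
            return Conclusion(id, INCONCLUSIVE, float(tops.mean()), threshold)
    elif rule == "majority":
        vals, counts = np.unique(assigns[assigns != -1], return_counts=True)
        if len(vals) and counts.max() >= 2:
            code = int(vals[counts.argmax()])
            agree = assigns == code
            cls, score = classes[code], float(tops[agree].mean())
        else:
            return Conclusion(id, INCONCLUSIVE, float(tops.max()), threshold)
    elif rule == "highest":
        best = int(tops.argmax())
        if assigns[best] == -1:
            return Conclusion(id, INCONCLUSIVE, float(tops[best]), threshold)
        cls, score = classes[assigns[best]], float(tops[best])
    else:
        raise ValueError(f"unknown rule {rule!r}")

    assigned = cls if score >= threshold else INCONCLUSIVE
    return Conclusion(id, assigned, score, threshold)


def predict_external(forest: IsomerForest, external: NormalizedTable) -> pd.DataFrame:
    """Vote profiles for an external batch preprocessed with the main
    batch's variables; all trees vote."""
    return predict_vote_profiles(forest, external.values)
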
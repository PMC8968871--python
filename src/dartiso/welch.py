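"""Univariate classification by per-bin Welch tests.

A test triplicate (one card's three replicates of one compound) is compared
to each candidate isomer's training data with an unequal-variance t test at
every variable.  A variable is "indistinguishable" when the test fails to
reject at the chosen confidence level; the comparison against the true
isomer should leave more bins indistinguishable than comparisons against
the wrong isomers.  Counts feed either a ROC sweep over count thresholds or
a max-count decision rule with a minimum-margin requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import Conclusion, INCONCLUSIVE
from .features import NormalizedTable, SCHEMES, Scheme

logger = logging.getLogger(__name__)


@dataclass
class WelchComparison:
    t: float
    df: float
    p: float
    confidence: float
    indistinguishable: bool


@dataclass
class CountProfile:
    """Indistinguishable-bin counts of one test triplicate vs each class."""

    card_id: str
    true_class: str
    counts: dict[str, int]
    total: int
    flags: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def welch_test_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise Welch t test between two groups.

    Returns (t, Welch-Satterthwaite df, two-sided p) per column.  When both
    groups have zero variance the convention is p = 1 for equal means and
    p = 0 otherwise (reachable on noiseless synthetic data).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    degenerate = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    if np.any(degenerate):
        equal = np.isclose(ma, mb)
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.where(equal, 0.0, np.inf * np.sign(ma - mb)), t)
        df = np.where(degenerate, na + nb - 2, df)
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return t, df, p


def welch_test(a: Sequence[float], b: Sequence[float], confidence: float = 95.0) -> WelchComparison:
    """Scalar Welch test; indistinguishable iff p > 1 - confidence/100.

    The boundary case p == alpha counts as distinguishable (a rejection).
    """
    if not 0 < confidence < 100:
        raise ValueError("confidence must be a percent in (0, 100)")
    t, df, p = welch_test_matrix(np.asarray(a)[:, None], np.asarray(b)[:, None])
    alpha = 1.0 - confidence / 100.0
    return WelchComparison(
        t=float(t[0]), df=float(df[0]), p=float(p[0]),
        confidence=confidence, indistinguishable=bool(p[0] > alpha),
    )


def count_indistinguishable(
    test_triplicate: pd.DataFrame,
    train_rows: pd.DataFrame,
    confidence: float,
) -> tuple[int, np.ndarray]:
    """Count variables where the triplicate is indistinguishable from the
    class training data; also return the per-variable boolean flags."""
    _, _, p = welch_test_matrix(test_triplicate.to_numpy(), train_rows.to_numpy())
    alpha = 1.0 - confidence / 100.0
    flags = p > alpha
    return int(flags.sum()), flags


def roc_from_counts(
    counts: Sequence[int], labels: Sequence[bool], total: int | None = None
) -> ROCResult:
    """ROC over integer count thresholds 0..total+1.

    A comparison is called positive when its indistinguishable count is at
    least the threshold; positives are comparisons against the true isomer.
    """
    counts = np.asarray(counts)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("need at least one positive and one negative comparison")
    if total is None:
        total = int(counts.max())
    thresholds = np.arange(0, total + 2)
    called = counts[None, :] >= thresholds[:, None]
    tpr = called[:, labels].mean(axis=1)
    fpr = called[:, ~labels].mean(axis=1)
    auc = float(-np.trapezoid(tpr, fpr))  # fpr runs 1 -> 0 along the sweep
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def average_rocs(rocs: Sequence[ROCResult]) -> ROCResult:
    """Pointwise average of FPR and TPR across replicate ROC curves.

    Curves are aligned on the threshold grid and padded at the top (where a
    shorter curve has already reached the origin).
    """
    n = max(len(r.thresholds) for r in rocs)
    thresholds = np.arange(0, n)
    fpr = np.zeros(n)
    tpr = np.zeros(n)
    for r in rocs:
        pad = n - len(r.thresholds)
        fpr += np.pad(r.fpr, (0, pad))
        tpr += np.pad(r.tpr, (0, pad))
    fpr /= len(rocs)
    tpr /= len(rocs)
    auc = float(-np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def classify_by_max_count(profile: CountProfile, min_difference: int = 0) -> Conclusion:
    """Assign the class with the most indistinguishable bins, provided its
    margin over the runner-up exceeds ``min_difference``; ties are
    inconclusive."""
    if len(profile.counts) < 2:
        raise ValueError("need >= 2 candidate classes")
    ranked = sorted(profile.counts.items(), key=lambda kv: kv[1], reverse=True)
    (best, c1), (_, c2) = ranked[0], ranked[1]
    if c1 == c2 or (c1 - c2) <= min_difference:
        assigned = INCONCLUSIVE
    else:
        assigned = best
    return Conclusion(id=profile.card_id, assigned=assigned, score=float(c1), threshold=float(min_difference))


def per_bin_accuracy(
    flagged: Iterable[tuple[np.ndarray, bool]], variables: Sequence[str]
) -> pd.Series:
    """Per-variable accuracy over labelled comparisons.

    Indistinguishable on a true-isomer comparison is a true positive;
    distinguishable on a wrong-isomer comparison is a true negative.
    """
    correct = np.zeros(len(variables))
    n = 0
    for flags, is_positive in flagged:
        correct += flags if is_positive else ~flags
        n += 1
    if n == 0:
        raise ValueError("no comparisons supplied")
    return pd.Series(correct / n, index=list(variables), name="accuracy")


# ---------------------------------------------------------------------------
# replicate harness

@dataclass
class WelchReplicate:
    confidence: float
    scheme: Scheme
    profiles: list[CountProfile]
    roc: ROCResult


@dataclass
class WelchRunResult:
    replicates: list[WelchReplicate]
    averaged_roc: ROCResult
    pooled_roc: ROCResult
    per_bin_accuracy: pd.Series


def _card_folds(metadata: pd.DataFrame, scope: Literal["full", "same_day"]):
    """Yield (card_id, test index, train index) with card-level exclusion."""
    for card_id in pd.unique(metadata["card_id"]):
        test = metadata.index[metadata["card_id"] == card_id]
        if scope == "full":
            train = metadata.index[metadata["card_id"] != card_id]
        else:
            day = metadata.loc[test[0], "week"]
            train = metadata.index[
                (metadata["week"] == day) & (metadata["card_id"] != card_id)
            ]
            if len(train) == 0:
                logger.warning("card %s is alone on its day; fold skipped", card_id)
                continue
        yield card_id, test, train


def compare_card(
    ntable: NormalizedTable,
    card_id: str,
    test_idx: pd.Index,
    train_idx: pd.Index,
    confidence: float,
) -> list[CountProfile]:
    """Count profiles for every test triplicate of one card."""
    meta = ntable.metadata
    classes = sorted(meta["isomer"].unique())
    profiles = []
    for true_class in sorted(meta.loc[test_idx, "isomer"].unique()):
        trip_idx = test_idx[meta.loc[test_idx, "isomer"] == true_class]
        trip = ntable.values.loc[trip_idx]
        counts, flags = {}, {}
        for cand in classes:
            rows = ntable.values.loc[train_idx[meta.loc[train_idx, "isomer"] == cand]]
            counts[cand], flags[cand] = count_indistinguishable(trip, rows, confidence)
        profiles.append(
            CountProfile(
                card_id=card_id, true_class=true_class, counts=counts,
                total=ntable.values.shape[1], flags=flags,
            )
        )
    return profiles


def _labelled(profiles: Sequence[CountProfile]) -> tuple[list[int], list[bool]]:
    counts, labels = [], []
    for pr in profiles:
        for cand, c in pr.counts.items():
            counts.append(c)
            labels.append(cand == pr.true_class)
    return counts, labels


def run_welch_replicates(
    ntables: dict[Scheme, NormalizedTable],
    n_replicates: int = 20,
    scope: Literal["full", "same_day"] = "full",
    seed: int = 0,
    confidence_range: tuple[float, float] = (90.0, 99.999),
) -> WelchRunResult:
    """The replicated leave-one-card-out Welch analysis.

    Each replicate draws a confidence level uniformly from
    ``confidence_range`` and picks one of the two normalisation schemes at
    random, then runs leave-one-card-out (or same-day-restricted) card
    comparisons.  Per-replicate ROC curves are kept and also averaged
    pointwise; a pooled curve over all replicates' comparisons is emitted as
    well.  Per-replicate RNG substreams are derived from the master seed by
    replicate counter.
    """
    any_table = next(iter(ntables.values()))
    total_vars = {s: t.values.shape[1] for s, t in ntables.items()}
    replicates: list[WelchReplicate] = []
    all_counts: list[int] = []
    all_labels: list[bool] = []
    acc_flags: list[tuple[np.ndarray, bool]] = []
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        confidence = float(rng.uniform(*confidence_range))
        scheme = SCHEMES[int(rng.integers(len(SCHEMES)))]
        ntable = ntables[scheme]
        profiles: list[CountProfile] = []
        for card_id, test_idx, train_idx in _card_folds(ntable.metadata, scope):
            profiles.extend(compare_card(ntable, card_id, test_idx, train_idx, confidence))
        counts, labels = _labelled(profiles)
        roc = roc_from_counts(counts, labels, total=total_vars[scheme])
        replicates.append(WelchReplicate(confidence, scheme, profiles, roc))
        all_counts.extend(counts)
        all_labels.extend(labels)
        for pr in profiles:
            for cand, fl in pr.flags.items():
                acc_flags.append((fl, cand == pr.true_class))
    averaged = average_rocs([r.roc for r in replicates])
    pooled = roc_from_counts(all_counts, all_labels, total=max(total_vars.values()))
    accuracy = per_bin_accuracy(acc_flags, list(any_table.values.columns))
    return WelchRunResult(
        replicates=replicates, averaged_roc=averaged, pooled_roc=pooled,
        per_bin_accuracy=accuracy,
    )
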
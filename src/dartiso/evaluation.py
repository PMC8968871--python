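"""Shared decision machinery: thresholds, rate tables and validation splits.

Every classifier in the package ends in the same forensic decision step: a
per-sample (or per-triplicate) score vector over the candidate isomers is
compared to an acceptance threshold swept from 0.50 to 0.95 in steps of
0.05.  The argmax class is reported only when its score meets the
threshold; otherwise the result is inconclusive.  Raising the threshold can
therefore only turn a conclusion into an inconclusive result, never flip it
to another class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: marker for a result that fails the acceptance criterion
INCONCLUSIVE = "inconclusive"

#: the swept acceptance thresholds
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class Conclusion:
    id: str
    assigned: str          # class label or INCONCLUSIVE
    score: float           # the quantity compared against the threshold
    threshold: float

    @property
    def conclusive(self) -> bool:
        return self.assigned != INCONCLUSIVE


def threshold_conclusion(
    scores: Mapping[str, float], threshold: float, id: str = ""
) -> Conclusion:
    """Assign the argmax class iff its score meets the threshold.

    The conclusive boundary is ``score >= threshold`` so that a unanimous
    0.50 vote is conclusive at the 0.50 threshold; argmax ties are
    inconclusive (a conservative forensic choice).
    """
    if len(scores) < 2:
        raise ValueError("need scores over >= 2 classes")
    ranked = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
    (best, s1), (_, s2) = ranked[0], ranked[1]
    if s1 == s2 or s1 < threshold:
        assigned = INCONCLUSIVE
    else:
        assigned = best
    return Conclusion(id=id, assigned=assigned, score=float(s1), threshold=float(threshold))


def rate_table(
    scored: Sequence[tuple[str, Mapping[str, float]]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Success / inconclusive / error fractions per acceptance threshold.

    ``scored`` is a sequence of (true class, score mapping) pairs.  Success
    is the fraction of correct conclusive calls, error the fraction of
    wrong conclusive calls, inconclusive the remainder; the three sum to 1
    in every row.
    """
    if len(scored) == 0:
        raise ValueError("no scored items supplied")
    rows = []
    for thr in thresholds:
        success = error = 0
        for truth, scores in scored:
            c = threshold_conclusion(scores, thr)
            if not c.conclusive:
                continue
            if c.assigned == truth:
                success += 1
            else:
                error += 1
        n = len(scored)
        rows.append(
            {
                "threshold": float(thr),
                "success": success / n,
                "inconclusive": (n - success - error) / n,
                "error": error / n,
            }
        )
    return pd.DataFrame(rows).set_index("threshold")


def rate_table_from_conclusions(
    items: Sequence[tuple[str, "Conclusion"]]
) -> dict[str, float]:
    """Single-threshold rates from ready-made conclusions."""
    if not items:
        raise ValueError("no conclusions supplied")
    n = len(items)
    success = sum(1 for truth, c in items if c.conclusive and c.assigned == truth)
    error = sum(1 for truth, c in items if c.conclusive and c.assigned != truth)
    return {
        "success": success / n,
        "inconclusive": (n - success - error) / n,
        "error": error / n,
    }


# ---------------------------------------------------------------------------
# validation splits

def split_80_20(
    metadata: pd.DataFrame, seed: int = 0, test_size: float = 0.2
) -> tuple[pd.Index, pd.Index]:
    """Stratified random 80/20 split; returns (train ids, test ids)."""
    if metadata.empty:
        raise ValueError("empty dataset")
    counts = metadata["isomer"].value_counts()
    stratify = metadata["isomer"]
    if (counts < 5).any():
        logger.warning("a class has < 5 samples; stratification is best-effort")
        if (counts < 2).any():
            stratify = None
    train, test = train_test_split(
        metadata.index, test_size=test_size, random_state=seed, stratify=stratify
    )
    return pd.Index(train), pd.Index(test)


def locso_splits(metadata: pd.DataFrame) -> list[tuple[str, pd.Index, pd.Index]]:
    """Leave-one-card-out folds: the test set is one QuickStrip card's worth
    of data (all isomers, all replicates)."""
    folds = []
    for card_id in pd.unique(metadata["card_id"]):
        test = metadata.index[metadata["card_id"] == card_id]
        train = metadata.index[metadata["card_id"] != card_id]
        folds.append((card_id, test, train))
    return folds


def same_day_splits(metadata: pd.DataFrame) -> list[tuple[str, pd.Index, pd.Index]]:
    """Per day, leave-one-card-out among that day's cards only.

    In the default design each weekly session is a single day, so "day"
    equals "week".  Single-card days are skipped with a warning.
    """
    folds = []
    for day in sorted(metadata["week"].unique()):
        day_meta = metadata[metadata["week"] == day]
        cards = pd.unique(day_meta["card_id"])
        if len(cards) < 2:
            logger.warning("day %s has a single card; fold skipped", day)
            continue
        for card_id in cards:
            test = day_meta.index[day_meta["card_id"] == card_id]
            train = day_meta.index[day_meta["card_id"] != card_id]
            folds.append((card_id, test, train))
    return folds
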
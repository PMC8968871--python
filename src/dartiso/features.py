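"""Variable selection, normalisation and screening statistics.

Selection works on a temporary percent-of-base-peak scale: each spectrum
(one sample at one voltage) is scaled so its base peak is 100%, and a bin is
kept when enough spectra show it at or above the percent-abundance
threshold.  The base-peak scale is used *only* for this selection step; raw
abundances pass through to normalisation.

Two normalisations are supported, both per sample per voltage and both
computed only over the finally selected bins:

* ``ion_current`` — divide by the summed abundance of the selected bins;
* ``vector_length`` — divide by the Euclidean norm of the selected bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinnedTable, VariableKey

logger = logging.getLogger(__name__)

Scheme = Literal["ion_current", "vector_length"]
SCHEMES: tuple[Scheme, ...] = ("ion_current", "vector_length")


@dataclass
class SelectionConfig:
    """Percent-abundance variable selection settings.

    ``reading`` selects between the two grammatical readings of the
    selection rule: ``count_meeting`` (default) keeps a bin when at least
    ``min_spectra`` spectra meet the percent threshold; ``count_failing``
    discards a bin when at least ``min_spectra`` spectra fail it.
    """

    pct_threshold: float = 0.3
    min_spectra: int = 50
    reading: Literal["count_meeting", "count_failing"] = "count_meeting"

    def __post_init__(self) -> None:
        if not 0 < self.pct_threshold <= 100:
            raise ValueError("pct_threshold must be in (0, 100]")
        if self.min_spectra < 1:
            raise ValueError("min_spectra must be >= 1")


@dataclass
class NormalizedTable:
    """One normalised abundance row per sample over the selected variables."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    scheme: Scheme

    def variables(self) -> list[VariableKey]:
        return [VariableKey.from_column(c) for c in self.values.columns]

    def columns_for_voltage(self, voltage: int) -> list[str]:
        return [c for c in self.values.columns if VariableKey.from_column(c).voltage == voltage]

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.metadata, self.values], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path)


def _percent_of_base_peak(table: BinnedTable) -> tuple[pd.DataFrame, int]:
    """Percent-of-base-peak values, spectrum-wise; returns (percent table
    stacked by voltage, number of counted spectra)."""
    blocks = []
    n_spectra = 0
    for v in table.voltages:
        cols = table.columns_for_voltage(v)
        block = table.abundance[cols].copy()
        base = block.max(axis=1)
        zero = base <= 0
        if zero.any():
            logger.warning(
                "%d all-zero spectra at %d V excluded from selection counting",
                int(zero.sum()), v,
            )
            block = block.loc[~zero]
            base = base.loc[~zero]
        n_spectra += len(block)
        pct = block.div(base, axis=0) * 100.0
        pct.columns = [VariableKey.from_column(c).bin_upper for c in cols]
        blocks.append(pct)
    return pd.concat(blocks, axis=0), n_spectra


def select_bins(table: BinnedTable, config: SelectionConfig | None = None) -> list[float]:
    """Voltage-agnostic candidate bins passing the percent-abundance rule.

    Counting is pooled over all spectra (every sample x voltage), so a bin
    that only appears in one voltage channel can still qualify.
    """
    config = config or SelectionConfig()
    pct, n_spectra = _percent_of_base_peak(table)
    # concat aligns the same bin across voltages into one column; a spectrum
    # whose voltage lacks the bin contributes NaN, i.e. "does not meet"
    counts = (pct >= config.pct_threshold).sum(axis=0)
    if config.reading == "count_meeting":
        keep = counts >= config.min_spectra
    else:  # count_failing: discard when >= min_spectra spectra fail
        keep = (n_spectra - counts) < config.min_spectra
    return sorted(float(b) for b in counts.index[keep])


def refine_per_voltage(
    table: BinnedTable,
    candidate_bins: Sequence[float],
    config: SelectionConfig | None = None,
) -> list[VariableKey]:
    """Keep a (bin, voltage) variable when the bin passes the same
    percent/count rule within that voltage's spectra alone."""
    config = config or SelectionConfig()
    candidates = set(candidate_bins)
    keys: list[VariableKey] = []
    for v in table.voltages:
        cols = table.columns_for_voltage(v)
        block = table.abundance[cols]
        base = block.max(axis=1)
        ok = base > 0
        pct = block.loc[ok].div(base.loc[ok], axis=0) * 100.0
        n = len(block)
        for c in cols:
            key = VariableKey.from_column(c)
            if key.bin_upper not in candidates:
                continue
            count = int((pct[c] >= config.pct_threshold).sum())
            if config.reading == "count_meeting":
                keep = count >= config.min_spectra
            else:
                keep = (n - count) < config.min_spectra
            if keep:
                keys.append(key)
    return sorted(keys)


def normalize(
    table: BinnedTable,
    variables: Sequence[VariableKey],
    scheme: Scheme = "ion_current",
) -> NormalizedTable:
    """Normalise raw abundances per sample per voltage over the selected bins.

    All-zero voltage segments stay all-zero (with a warning) so degraded
    samples still flow through to the classifiers.
    """
    if not variables:
        raise ValueError("no variables selected")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    cols = [k.column for k in sorted(set(variables))]
    missing = [c for c in cols if c not in table.abundance.columns]
    sub = table.abundance.reindex(columns=cols, fill_value=0.0).astype(float).copy()
    if missing:
        logger.warning("%d selected variables absent from table, filled with 0", len(missing))
    for v in sorted({k.voltage for k in variables}):
        vcols = [c for c in cols if VariableKey.from_column(c).voltage == v]
        block = sub[vcols]
        if scheme == "ion_current":
            denom = block.sum(axis=1)
        else:
            denom = np.sqrt((block ** 2).sum(axis=1))
        zero = denom <= 0
        if zero.any():
            logger.warning("%d all-zero %d V segments left as zeros", int(zero.sum()), v)
        denom = denom.where(~zero, 1.0)
        sub.loc[:, vcols] = block.div(denom, axis=0)
    return NormalizedTable(values=sub, metadata=table.metadata.loc[sub.index], scheme=scheme)


# ---------------------------------------------------------------------------
# multiway ANOVA

_FACTORS = ("isomer", "week", "volume")


def _term_names(factors: Sequence[str]) -> list[tuple[str, ...]]:
    terms = [(f,) for f in factors]
    k = len(factors)
    for i in range(k):
        for j in range(i + 1, k):
            terms.append((factors[i], factors[j]))
    if k == 3:
        terms.append(tuple(factors))
    return terms


def _dummies(meta: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    cells = meta[list(term)].astype(str).agg(":".join, axis=1)
    return pd.get_dummies(cells).to_numpy(dtype=float)


def multiway_anova(
    ntable: NormalizedTable,
    factors: Sequence[str] = _FACTORS,
) -> pd.DataFrame:
    """Per-variable multi-factor ANOVA with all interactions.

    Sums of squares are sequential (Type I); the study design is balanced so
    the SS types coincide.  A warning is emitted for unbalanced input, and
    factors with a single level are skipped.  Returns one row per variable
    with ``F_<term>``, ``p_<term>`` and ``df_<term>`` columns.
    """
    meta = ntable.metadata
    active = []
    for f in factors:
        if meta[f].nunique() < 2:
            logger.warning("factor %r has a single level; skipped", f)
        else:
            active.append(f)
    if not active:
        raise ValueError("no factor with >= 2 levels")
    cell_sizes = meta.groupby(active, observed=True).size()
    if cell_sizes.nunique() > 1:
        logger.warning("design is unbalanced; sequential (Type I) SS are order-dependent")

    terms = _term_names(active)
    n = len(meta)
    Y = ntable.values.to_numpy(dtype=float)

    def _basis(X: np.ndarray) -> np.ndarray:
        # orthonormal basis of span(X), robust to the redundant dummy columns
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        return U[:, s > s[0] * max(X.shape) * np.finfo(float).eps]

    # cumulative projections: intercept, then each term's cell dummies
    X = np.ones((n, 1))
    prev_rank = 1
    prev_fit = np.broadcast_to(Y.mean(axis=0), Y.shape)
    ss_prev = np.zeros(Y.shape[1])
    rows: dict[str, np.ndarray] = {}
    dfs: dict[str, int] = {}
    for term in terms:
        X = np.hstack([X, _dummies(meta, term)])
        U = _basis(X)
        rank = U.shape[1]
        fit = U @ (U.T @ Y)
        ss = ((fit - Y.mean(axis=0)) ** 2).sum(axis=0)
        name = ":".join(term)
        rows[name] = ss - ss_prev
        dfs[name] = rank - prev_rank
        ss_prev, prev_rank, prev_fit = ss, rank, fit
    sse = ((Y - prev_fit) ** 2).sum(axis=0)
    dfe = n - prev_rank
    if dfe <= 0:
        raise ValueError("no residual degrees of freedom for the full model")
    mse = sse / dfe

    out = {}
    for name, ss in rows.items():
        df = dfs[name]
        if df <= 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df) / mse
        F = np.where(mse > 0, F, np.nan)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = stats.f.sf(F, df, dfe)
        out[f"df_{name}"] = df
    result = pd.DataFrame(out, index=ntable.values.columns.copy().rename("variable"))
    result["df_residual"] = dfe
    return result


# ---------------------------------------------------------------------------
# descriptive outputs

def weekly_profiles(
    ntable: NormalizedTable,
    mode: Literal["per_week", "accumulating"] = "per_week",
) -> pd.DataFrame:
    """Mean and sd per variable x class x week.

    ``per_week`` summarises each week alone; ``accumulating`` summarises the
    growing data set weeks 1..k, which is how batch drift is shown to
    stabilise as data accumulate.
    """
    meta = ntable.metadata
    weeks = sorted(meta["week"].unique())
    frames = []
    for k, week in enumerate(weeks):
        if mode == "per_week":
            mask = meta["week"] == week
        elif mode == "accumulating":
            mask = meta["week"].isin(weeks[: k + 1])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        sub = ntable.values.loc[mask]
        grp = sub.groupby(meta.loc[mask, "isomer"], observed=True)
        mean = grp.mean().stack()
        sd = grp.std(ddof=1).stack()
        n = grp.size()
        frame = pd.DataFrame({"mean": mean, "sd": sd})
        frame.index.names = ["isomer", "variable"]
        frame = frame.reset_index()
        frame["week"] = week
        frame["n"] = frame["isomer"].map(n)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[["variable", "isomer", "week", "mean", "sd", "n"]]


def correlation_matrix(ntable: NormalizedTable) -> pd.DataFrame:
    """Pearson correlations between variables; zero-variance variables are
    recorded as NaN (undefined) off the diagonal."""
    if len(ntable.values) < 3:
        raise ValueError("need >= 3 samples for a correlation matrix")
    corr = ntable.values.corr()
    np.fill_diagonal(corr.values, 1.0)
    return corr
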
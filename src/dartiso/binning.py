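"""Binned representation of centroided multi-voltage spectra.

A DART-ToF analysis produces one centroided spectrum per Orifice-1 voltage
(30, 60 and 90 V via function switching).  All downstream chemometrics work
on a single wide table with one row per sample and one column per
(m/z bin, voltage) combination.  Bins are 0.025 Da wide and are named for
their *upper* limit: the 109.050 bin covers the half-open interval
(109.025, 109.050].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BIN_WIDTH = 0.025
DEFAULT_ABUNDANCE_FLOOR = 120.0

#: metadata columns written in front of the abundance columns of the wide CSV
METADATA_COLUMNS = ("isomer", "week", "card", "card_id", "replicate", "volume", "batch")


class VoltageMismatchError(ValueError):
    """Raised when two spectra from different voltage channels are combined."""


class MissingVoltageError(ValueError):
    """Raised when a sample lacks a spectrum for a configured voltage."""


@dataclass(frozen=True, order=True)
class VariableKey:
    """One analysis variable: an m/z bin at one Orifice-1 voltage.

    ``bin_upper`` is the upper limit of the 0.025 Da bin (the bin's name);
    the bin covers ``(bin_upper - width, bin_upper]``.
    """

    bin_upper: float
    voltage: int

    @property
    def column(self) -> str:
        return f"{self.bin_upper:.3f}_{self.voltage}V"

    @classmethod
    def from_column(cls, name: str) -> "VariableKey":
        mz, volt = name.rsplit("_", 1)
        if not volt.endswith("V"):
            raise ValueError(f"not a variable column name: {name!r}")
        return cls(bin_upper=float(mz), voltage=int(volt[:-1]))


@dataclass
class CentroidSpectrum:
    """One voltage channel of one analysis: centroided (m/z, abundance) peaks."""

    sample_id: str
    voltage: int
    mz: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mz.shape != self.abundance.shape:
            raise ValueError("mz and abundance must have the same length")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.abundance = self.abundance[order]

    def __len__(self) -> int:
        return len(self.mz)


def bin_peak(mz: float, width: float = BIN_WIDTH) -> float:
    """Return the name (upper limit) of the bin containing ``mz``.

    The convention is left-open/right-closed, so a centroid exactly on a
    bin boundary belongs to the bin named after it: 109.050 -> 109.050,
    while 109.0501 -> 109.075.
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    # small tolerance so boundary values are not pushed up by float error
    k = math.ceil(mz / width - 1e-6)
    return round(k * width, 6)


def bin_peaks(mz: np.ndarray, width: float = BIN_WIDTH) -> np.ndarray:
    """Vectorised :func:`bin_peak`."""
    mz = np.asarray(mz, dtype=float)
    if np.any(mz <= 0):
        raise ValueError("m/z values must be positive")
    k = np.ceil(mz / width - 1e-6)
    return np.round(k * width, 6)


def _binned_series(spectrum: CentroidSpectrum, width: float = BIN_WIDTH) -> pd.Series:
    """Sum peak abundances per bin (ion current is additive)."""
    if len(spectrum) == 0:
        return pd.Series(dtype=float)
    bins = bin_peaks(spectrum.mz, width)
    return pd.Series(spectrum.abundance).groupby(bins).sum()


def background_subtract(
    sample: CentroidSpectrum,
    blank: CentroidSpectrum,
    width: float = BIN_WIDTH,
) -> CentroidSpectrum:
    """Subtract a solvent-blank spectrum from a sample spectrum.

    Both spectra are binned first (centroid m/z values never match exactly);
    matched bins are subtracted and clamped at zero, since negative ion
    abundances are physically meaningless.
    """
    if sample.voltage != blank.voltage:
        raise VoltageMismatchError(
            f"sample at {sample.voltage} V, blank at {blank.voltage} V"
        )
    s = _binned_series(sample, width)
    b = _binned_series(blank, width).reindex(s.index, fill_value=0.0)
    corrected = np.maximum(0.0, s.values - b.values)
    return CentroidSpectrum(sample.sample_id, sample.voltage, s.index.values, corrected)


def apply_abundance_floor(
    spectrum: CentroidSpectrum, floor: float = DEFAULT_ABUNDANCE_FLOOR
) -> CentroidSpectrum:
    """Drop centroids below the reporting floor (default 120 counts, inclusive keep)."""
    if floor < 0:
        raise ValueError("floor must be non-negative")
    keep = spectrum.abundance >= floor
    return CentroidSpectrum(
        spectrum.sample_id, spectrum.voltage, spectrum.mz[keep], spectrum.abundance[keep]
    )


@dataclass
class BinnedTable:
    """Wide raw-abundance table: one row per sample, one column per bin x voltage.

    ``abundance`` is indexed by sample_id with columns named like
    ``109.050_30V``; ``metadata`` is indexed by sample_id.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def voltages(self) -> list[int]:
        return sorted({VariableKey.from_column(c).voltage for c in self.abundance.columns})

    def variables(self) -> list[VariableKey]:
        return [VariableKey.from_column(c) for c in self.abundance.columns]

    def columns_for_voltage(self, voltage: int) -> list[str]:
        return [c for c in self.abundance.columns if VariableKey.from_column(c).voltage == voltage]

    # --- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        meta_cols = [c for c in METADATA_COLUMNS if c in self.metadata.columns]
        wide = pd.concat([self.metadata[meta_cols], self.abundance], axis=1)
        wide.index.name = "sample_id"
        # %.17g guarantees a bit-exact float64 round trip through the CSV
        wide.to_csv(path, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "BinnedTable":
        wide = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
        meta_cols = [c for c in wide.columns if c in METADATA_COLUMNS]
        value_cols = [c for c in wide.columns if c not in META_NON_VALUE]
        return cls(abundance=wide[value_cols].astype(float), metadata=wide[meta_cols])


META_NON_VALUE = set(METADATA_COLUMNS)


def assemble_table(
    spectra: Iterable[CentroidSpectrum],
    metadata: pd.DataFrame,
    voltages: Sequence[int] | None = None,
    width: float = BIN_WIDTH,
) -> BinnedTable:
    """Assemble the single wide table from all per-voltage spectra.

    Every sample must contribute one spectrum per configured voltage.
    Multiple centroids falling into one bin are summed; bins absent from a
    spectrum are stored as 0 so every row is complete.
    """
    spectra = list(spectra)
    if voltages is None:
        voltages = sorted({s.voltage for s in spectra})
    by_sample: dict[str, dict[int, CentroidSpectrum]] = {}
    for s in spectra:
        by_sample.setdefault(s.sample_id, {})[s.voltage] = s

    meta = metadata.copy()
    if meta.index.name != "sample_id":
        meta = meta.set_index("sample_id")
    rows = {}
    for sample_id in meta.index:
        channels = by_sample.get(sample_id, {})
        row = {}
        for v in voltages:
            if v not in channels:
                raise MissingVoltageError(f"sample {sample_id!r} has no {v} V spectrum")
            series = _binned_series(channels[v], width)
            for b, a in series.items():
                row[VariableKey(b, v).column] = a
        rows[sample_id] = row

    abundance = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    abundance = abundance.reindex(meta.index)
    keys = [VariableKey.from_column(c) for c in abundance.columns]
    order = np.argsort(
        np.array([(k.voltage, k.bin_upper) for k in keys], dtype=[("v", int), ("b", float)]),
        order=("v", "b"),
    )
    abundance = abundance.iloc[:, order]
    abundance.index.name = "sample_id"
    return BinnedTable(abundance=abundance, metadata=meta)
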
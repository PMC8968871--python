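"""Synthetic multi-voltage DART-ToF spectra with the study's design structure.

The emulated experiment: three positional ring isomers (ortho/meta/para) of
one compound are deposited on QuickStrip cards and analysed by DART-ToF with
in-source CID at three Orifice-1 voltages.  Four cards are run per week over
eight weeks; each card carries a triplicate of every isomer; two cards per
week receive 3 uL depositions and two receive 6 uL.  That yields 96 analyses
per compound and 288 per isomer set.

The generative model is multiplicative on ion abundance (ambient-ionisation
intensities are positive and right-skewed, so all random effects are
lognormal):

    abundance(s, f) = exp( mu_f + class_offset(c(s), f)
                           + sens_f * log volume_factor(vol(s))
                           + load_f * W_week(s) + U_week(s),f
                           + eps_{s,f} )

with a per-week factor ``W`` shared across fragments (scaled by a
per-fragment loading, which induces the positive inter-variable correlation
seen in real weekly batches), a per-(fragment, week) idiosyncratic drift
``U``, and i.i.d. per-peak noise ``eps``.  Centroid m/z values get a small
uniform mass jitter, bounded well inside one 0.025 Da bin by default.
A handful of "junk" peaks per spectrum sit just above the 120-count
centroiding floor but below any percent-abundance selection threshold.

An external validation batch reuses the fragment catalogue but applies a
global intensity scale (a tenfold concentration change), per-card drift in
place of per-week drift (the cards were run on scattered days), and its own
deposition-volume rule (three 10 uL cards, then 3 uL cards).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import CentroidSpectrum

DEFAULT_SEED = 20210317
DEFAULT_CLASSES = ("ortho", "meta", "para")


class ConfigurationError(ValueError):
    """Raised for non-positive design counts or inconsistent model settings."""


@dataclass
class DesignConfig:
    """The sampling design of the main data set."""

    n_classes: int = 3
    n_weeks: int = 8
    cards_per_week: int = 4
    replicates_per_card: int = 3
    #: deposition volume per card slot within a week, cycled over cards
    volumes: tuple[float, ...] = (3.0, 3.0, 6.0, 6.0)
    voltages: tuple[int, ...] = (30, 60, 90)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_weeks", "cards_per_week", "replicates_per_card"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not self.volumes or not self.voltages:
            raise ConfigurationError("volumes and voltages must be non-empty")

    @property
    def classes(self) -> tuple[str, ...]:
        if self.n_classes <= len(DEFAULT_CLASSES):
            return DEFAULT_CLASSES[: self.n_classes]
        return tuple(f"iso{i + 1}" for i in range(self.n_classes))

    @property
    def samples_per_class(self) -> int:
        return self.n_weeks * self.cards_per_week * self.replicates_per_card


@dataclass(frozen=True)
class Fragment:
    """One catalogue fragment: a true m/z emitted at one voltage.

    ``log_mean`` is the mean log-abundance for the reference condition;
    ``class_offsets`` shift it per isomer class (all zeros = a fragment that
    carries no isomer information, the negative control for importance and
    ANOVA checks).  ``week_loading`` couples the fragment to the shared
    weekly factor; ``volume_sensitivity`` lets deposition volume change the
    *relative* composition (response is not perfectly linear in volume), so
    the volume factor survives normalisation for some fragments.
    """

    mz: float
    voltage: int
    log_mean: float
    class_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)
    week_loading: float = 1.0
    volume_sensitivity: float = 1.0
    label: str = ""


@dataclass
class SpectrumModel:
    """Statistical model of the centroided spectra."""

    fragments: list[Fragment]
    classes: tuple[str, ...] = DEFAULT_CLASSES
    week_effect_sd: float = 0.25      # idiosyncratic per-(fragment, week) lognormal scale
    shared_week_sd: float = 0.30      # per-week factor shared across fragments
    volume_effect: dict[float, float] = field(
        default_factory=lambda: {3.0: 1.0, 6.0: 1.9, 10.0: 2.6}
    )
    noise_sd: float = 0.35            # per-peak lognormal noise
    #: per-class multiplier on noise_sd: the isomers fragment with different
    #: reproducibility (ortho-effect pathways are the most variable), so the
    #: class covariances are genuinely unequal
    class_noise_scale: tuple[float, ...] = (1.0, 1.4, 0.75)
    mass_jitter: float = 0.005        # uniform +- jitter on centroid m/z, Da
    n_junk_peaks: int = 6             # noise-floor peaks per spectrum
    junk_abundance: tuple[float, float] = (130.0, 260.0)
    junk_mz_range: tuple[float, float] = (80.0, 200.0)

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ConfigurationError("fragment catalogue is empty")
        for f in self.fragments:
            if len(f.class_offsets) != len(self.classes):
                raise ConfigurationError(
                    f"fragment {f.mz}@{f.voltage}V has {len(f.class_offsets)} class "
                    f"offsets for {len(self.classes)} classes"
                )
        if any(sd < 0 for sd in (self.week_effect_sd, self.shared_week_sd, self.noise_sd)):
            raise ConfigurationError("standard deviations must be non-negative")
        if len(self.class_noise_scale) != len(self.classes):
            raise ConfigurationError("class_noise_scale must have one entry per class")

    def fragments_at(self, voltage: int) -> list[Fragment]:
        return [f for f in self.fragments if f.voltage == voltage]

    @property
    def voltages(self) -> tuple[int, ...]:
        return tuple(sorted({f.voltage for f in self.fragments}))

    def informative_fragments(self) -> list[Fragment]:
        return [f for f in self.fragments if any(o != 0.0 for o in f.class_offsets)]


@dataclass
class BatchShift:
    """How the external validation batch differs from the main batch."""

    intensity_scale: float = 10.0   # tenfold concentration change
    drift_scale: float = 1.5        # extra card-level drift relative to weekly drift
    #: deposition volume per card, cycled; defaults mirror three 10 uL cards
    #: followed by 3 uL cards
    volumes: tuple[float, ...] = (10.0, 10.0, 10.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0)

    @classmethod
    def identity(cls, volumes: tuple[float, ...] = (3.0, 3.0, 6.0, 6.0)) -> "BatchShift":
        return cls(intensity_scale=1.0, drift_scale=1.0, volumes=volumes)


# ---------------------------------------------------------------------------
# default catalogue

# class-contrast patterns (per-class multipliers of the effect size); varying
# the pattern across fragments keeps all three classes mutually separable
_P1 = (1.0, 0.0, -1.0)
_P2 = (-1.0, 1.0, 0.0)
_P3 = (0.0, -1.0, 1.0)
_P4 = (1.0, -1.0, 0.0)


def _off(pattern: tuple[float, ...], size: float) -> tuple[float, ...]:
    return tuple(size * p for p in pattern)


def default_model() -> SpectrumModel:
    """The default fragment catalogue for a phenethylamine-like isomer set.

    Abundances are on a natural-log scale (exp(11.8) ~ 1.3e5 counts for the
    protonated molecule at 30 V).  The protonated molecule carries no class
    effect at any voltage — positional isomers share the same [M+H]+ — while
    the discriminating information lives in the is-CID fragments, partly in
    low-abundance bins near the percent-abundance selection threshold.
    """
    # true m/z values sit >= 0.005 Da inside their 0.025 Da bin, so the
    # default mass jitter never splits a fragment across two bins
    frags = [
        # [M+H]+ : zero class effect at every voltage (negative control)
        Fragment(168.118, 30, 11.8, _off(_P1, 0.0), 0.9, 0.95, "zero-effect"),
        Fragment(168.118, 60, 10.8, _off(_P1, 0.0), 0.8, 1.00, "zero-effect"),
        Fragment(168.118, 90, 9.5, _off(_P1, 0.0), 0.7, 1.05, "zero-effect"),
        # water/amine-loss fragment, weak effect
        Fragment(150.110, 30, 9.8, _off(_P1, 0.12), 0.6, 1.10),
        Fragment(150.110, 60, 10.3, _off(_P1, 0.22), 0.7, 0.90),
        Fragment(150.110, 90, 9.6, _off(_P1, 0.28), 0.9, 1.00),
        # amine loss: strongest para/ortho separator, attenuated at 90 V
        Fragment(137.110, 30, 9.0, _off(_P1, 0.40), 0.5, 1.10, "strong-effect"),
        Fragment(137.110, 60, 10.0, _off(_P1, 0.50), 0.6, 0.85, "strong-effect"),
        Fragment(137.110, 90, 9.3, _off(_P1, 0.30), 0.8, 1.00),
        # H2 loss from the amine-loss fragment
        Fragment(135.085, 60, 8.8, _off(_P2, 0.40), 1.0, 1.00),
        Fragment(135.085, 90, 9.2, _off(_P2, 0.50), 0.9, 1.10),
        # phenyl-cyclopropyl cation, low abundance, ortho-effect driven
        Fragment(115.085, 60, 7.3, _off(_P3, 0.35), 0.5, 1.05, "low-abundance"),
        Fragment(115.085, 90, 8.2, _off(_P3, 0.60), 0.6, 0.95, "low-abundance"),
        # rearrangement ion, low abundance with a class effect
        Fragment(160.135, 60, 7.0, _off(_P4, 0.50), 0.4, 1.15, "low-abundance"),
        # further CID products at 90 V
        Fragment(128.085, 90, 7.4, _off(_P4, 0.45), 0.5, 0.90, "low-abundance"),
        Fragment(91.060, 90, 8.8, _off(_P2, 0.20), 1.0, 1.00),
        # present only at 30 V (exercises the per-voltage refinement)
        Fragment(119.085, 30, 8.4, _off(_P3, 0.25), 0.8, 1.00),
    ]
    frags += _minor_fragments()
    return SpectrumModel(fragments=frags)


def _minor_fragments(n: int = 48) -> list[Fragment]:
    """A deterministic tail of minor ions above the selection threshold.

    Real DART spectra carry dozens of minor reproducible peaks; most are
    uninformative for the isomer, a minority carry a small class effect.
    This tail is what makes the multivariate problem realistically wide
    (p of order 60 instead of a curated handful of fragments).
    """
    rng = np.random.default_rng(987654321)  # catalogue constant, not a run seed
    patterns = (_P1, _P2, _P3, _P4)
    taken: set[float] = set()
    frags: list[Fragment] = []
    i = 0
    while len(frags) < n:
        i += 1
        # stable bin interior: 10 mDa below a random 0.025 Da bin edge
        bin_upper = round(rng.integers(80 * 40, 320 * 40) * 0.025, 6)
        voltage = (30, 60, 90)[int(rng.integers(3))]
        if (bin_upper, voltage) in taken:
            continue
        taken.add((bin_upper, voltage))
        log_mean = float(rng.uniform(7.0, 9.0))
        if rng.uniform() < 0.3:   # a minority carries a small class effect
            size = float(rng.uniform(0.06, 0.18))
            offsets = _off(patterns[int(rng.integers(4))], size)
        else:
            offsets = _off(_P1, 0.0)
        frags.append(
            Fragment(
                mz=round(bin_upper - 0.010, 6),
                voltage=voltage,
                log_mean=log_mean,
                class_offsets=offsets,
                week_loading=float(rng.uniform(0.3, 1.0)),
                volume_sensitivity=float(rng.uniform(0.85, 1.15)),
                label="minor",
            )
        )
    return frags


# ---------------------------------------------------------------------------
# operations

def generate_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """One metadata record per (class, week, card, replicate).

    Cards are shared across classes (each QuickStrip card carries a
    triplicate of every isomer); the deposition volume is a property of the
    card, assigned by cycling ``config.volumes`` over the card slots.
    """
    config = config or DesignConfig()
    records = []
    for week in range(1, config.n_weeks + 1):
        for card in range(1, config.cards_per_week + 1):
            volume = config.volumes[(card - 1) % len(config.volumes)]
            card_id = f"W{week}C{card}"
            for cls in config.classes:
                for rep in range(1, config.replicates_per_card + 1):
                    records.append(
                        {
                            "sample_id": f"{cls}_w{week}c{card}r{rep}",
                            "isomer": cls,
                            "week": week,
                            "card": card,
                            "card_id": card_id,
                            "replicate": rep,
                            "volume": volume,
                            "batch": "main",
                        }
                    )
    return pd.DataFrame.from_records(records)


def _volume_factor(model: SpectrumModel, volume: float) -> float:
    try:
        return model.volume_effect[volume]
    except KeyError:
        raise ConfigurationError(
            f"no volume effect configured for {volume} uL; known: "
            f"{sorted(model.volume_effect)}"
        ) from None


def _draw_drift(
    model: SpectrumModel,
    units: Sequence,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> dict:
    """Per-(drift unit, fragment) log effects; the unit is a week or a card."""
    drift = {}
    for u in units:
        shared = rng.normal(0.0, model.shared_week_sd * scale)
        idio = rng.normal(0.0, model.week_effect_sd * scale, size=len(model.fragments))
        drift[u] = {
            (f.mz, f.voltage): f.week_loading * shared + idio[i]
            for i, f in enumerate(model.fragments)
        }
    return drift


def _simulate_one(
    row: pd.Series,
    model: SpectrumModel,
    drift: dict,
    drift_key,
    rng: np.random.Generator,
    intensity_scale: float = 1.0,
) -> list[CentroidSpectrum]:
    class_idx = model.classes.index(row["isomer"])
    vol_factor = _volume_factor(model, row["volume"])
    noise_sd = model.noise_sd * model.class_noise_scale[class_idx]
    out = []
    for voltage in model.voltages:
        frags = model.fragments_at(voltage)
        mzs, abunds = [], []
        for f in frags:
            log_ab = (
                f.log_mean
                + f.class_offsets[class_idx]
                + f.volume_sensitivity * np.log(vol_factor)
                + drift[drift_key][(f.mz, f.voltage)]
                + rng.normal(0.0, noise_sd)
                + np.log(intensity_scale)
            )
            jitter = rng.uniform(-model.mass_jitter, model.mass_jitter)
            mzs.append(f.mz + jitter)
            abunds.append(np.exp(log_ab))
        for _ in range(model.n_junk_peaks):
            mzs.append(rng.uniform(*model.junk_mz_range))
            abunds.append(rng.uniform(*model.junk_abundance) * intensity_scale)
        out.append(CentroidSpectrum(row["sample_id"], voltage, np.array(mzs), np.array(abunds)))
    return out


def simulate_spectra(
    design: pd.DataFrame,
    model: SpectrumModel,
    seed: int = DEFAULT_SEED,
) -> list[CentroidSpectrum]:
    """Simulate one centroided spectrum per sample per voltage.

    Deterministic given ``seed``: the weekly drift surface is drawn first
    (weeks in sorted order), then samples are visited in design order.
    """
    if design.empty:
        raise ConfigurationError("design is empty")
    rng = np.random.default_rng(seed)
    weeks = sorted(design["week"].unique())
    drift = _draw_drift(model, weeks, rng)
    spectra: list[CentroidSpectrum] = []
    for _, row in design.iterrows():
        spectra.extend(_simulate_one(row, model, drift, row["week"], rng))
    return spectra


def generate_external_batch(
    model: SpectrumModel,
    n_cards: int = 11,
    shift: BatchShift | None = None,
    seed: int = DEFAULT_SEED + 1,
    replicates_per_card: int = 3,
) -> tuple[list[CentroidSpectrum], pd.DataFrame]:
    """An external validation batch: same catalogue, shifted conditions.

    Each card is its own drift unit (the cards were run on scattered days),
    with drift standard deviations scaled by ``shift.drift_scale`` and all
    intensities scaled by ``shift.intensity_scale``.
    """
    shift = shift or BatchShift()
    if n_cards < 1:
        raise ConfigurationError("n_cards must be >= 1")
    records = []
    for card in range(1, n_cards + 1):
        volume = shift.volumes[(card - 1) % len(shift.volumes)]
        card_id = f"X{card}"
        for cls in model.classes:
            for rep in range(1, replicates_per_card + 1):
                records.append(
                    {
                        "sample_id": f"ext_{cls}_c{card}r{rep}",
                        "isomer": cls,
                        "week": 100 + card,  # pseudo-week: one card per day
                        "card": card,
                        "card_id": card_id,
                        "replicate": rep,
                        "volume": volume,
                        "batch": "external",
                    }
                )
    metadata = pd.DataFrame.from_records(records)
    rng = np.random.default_rng(seed)
    cards = sorted(metadata["card"].unique())
    drift = _draw_drift(model, cards, rng, scale=shift.drift_scale)
    spectra: list[CentroidSpectrum] = []
    for _, row in metadata.iterrows():
        spectra.extend(
            _simulate_one(row, model, drift, row["card"], rng, shift.intensity_scale)
        )
    return spectra, metadata


# ---------------------------------------------------------------------------
# serialization

def write_spectra_csv(spectra: Sequence[CentroidSpectrum], path: str | Path) -> None:
    """Long format: sample_id, voltage, mz, abundance."""
    frames = [
        pd.DataFrame(
            {"sample_id": s.sample_id, "voltage": s.voltage, "mz": s.mz, "abundance": s.abundance}
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[CentroidSpectrum]:
    long = pd.read_csv(path)
    out = []
    for (sample_id, voltage), grp in long.groupby(["sample_id", "voltage"], sort=False):
        out.append(
            CentroidSpectrum(str(sample_id), int(voltage), grp["mz"].values, grp["abundance"].values)
        )
    return out


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


def write_sidecar(config: DesignConfig, seed: int, path: str | Path) -> None:
    """JSON sidecar recording the design and the seed actually used."""
    payload = {"design": asdict(config), "seed": seed}
    Path(path).write_text(json.dumps(payload, indent=2))
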
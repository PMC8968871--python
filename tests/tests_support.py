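"""Shared builders for classifier tests."""

import numpy as np

from dartiso.binning import assemble_table
from dartiso.features import normalize
from dartiso.synthetic import (
    DesignConfig,
    Fragment,
    SpectrumModel,
    generate_design,
    simulate_spectra,
)


def separable_model(noise_sd: float = 0.0) -> SpectrumModel:
    """Widely separated class means, optional small noise."""
    frags = [
        Fragment(110.010, 30, 9.0, (2.0, 0.0, -2.0)),
        Fragment(120.010, 30, 9.0, (-2.0, 2.0, 0.0)),
        Fragment(130.010, 30, 9.0, (0.0, -2.0, 2.0)),
        Fragment(140.010, 30, 10.0, (0.0, 0.0, 0.0)),
    ]
    return SpectrumModel(
        fragments=frags, noise_sd=noise_sd, week_effect_sd=0.0, shared_week_sd=0.0,
        mass_jitter=0.0, n_junk_peaks=0,
        volume_effect={3.0: 1.0, 6.0: 1.0, 10.0: 1.0},
        class_noise_scale=(1.0, 1.0, 1.0),
    )


def build_separable_ntables(seed: int = 0, noise_sd: float = 0.0):
    design = generate_design(DesignConfig(n_weeks=2, cards_per_week=2))
    spectra = simulate_spectra(design, separable_model(noise_sd), seed=seed)
    binned = assemble_table(spectra, design, voltages=[30])
    variables = binned.variables()
    return {s: normalize(binned, variables, s) for s in ("ion_current", "vector_length")}
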
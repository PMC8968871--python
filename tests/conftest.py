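import logging

import pytest

from dartiso.binning import apply_abundance_floor, assemble_table
from dartiso.features import SelectionConfig, normalize, refine_per_voltage, select_bins
from dartiso.synthetic import DesignConfig, default_model, generate_design, simulate_spectra

logging.getLogger("dartiso").setLevel(logging.ERROR)

SEED = 20210317


def build_dataset(seed=SEED, design_config=None, model=None, floor=120.0,
                  selection=None):
    """Simulate, bin and select; returns (model, variables, binned, ntables)."""
    design_config = design_config or DesignConfig()
    model = model or default_model()
    design = generate_design(design_config)
    spectra = [apply_abundance_floor(s, floor) for s in simulate_spectra(design, model, seed=seed)]
    binned = assemble_table(spectra, design, voltages=design_config.voltages)
    sel = selection or SelectionConfig()
    variables = refine_per_voltage(binned, select_bins(binned, sel), sel)
    ntables = {s: normalize(binned, variables, s) for s in ("ion_current", "vector_length")}
    return model, variables, binned, ntables


@pytest.fixture(scope="session")
def dataset():
    """The default full study design, simulated once per session."""
    return build_dataset()


@pytest.fixture(scope="session")
def ion_current(dataset):
    return dataset[3]["ion_current"]


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced 2-week design for the cheaper structural tests."""
    cfg = DesignConfig(n_weeks=2, cards_per_week=2, volumes=(3.0, 6.0))
    return build_dataset(seed=7, design_config=cfg, selection=SelectionConfig(min_spectra=20))
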
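"""Small CSV readers shared by the CLI."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .binning import METADATA_COLUMNS
from .features import NormalizedTable


def read_normalized_csv(path: str | Path, scheme: str = "ion_current") -> NormalizedTable:
    wide = pd.read_csv(path, index_col="sample_id")
    meta_cols = [c for c in wide.columns if c in METADATA_COLUMNS]
    value_cols = [c for c in wide.columns if c not in METADATA_COLUMNS]
    return NormalizedTable(
        values=wide[value_cols].astype(float), metadata=wide[meta_cols], scheme=scheme
    )
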
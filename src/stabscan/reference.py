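"""Published reference measurements shipped with the package.

``load_reference_fits`` returns the experimentally measured two-state fit
parameters for the AR ligand-binding domain: wild type plus four AIS
mutants (I738T, C807Y — PAIS; W752R, L813F — CAIS). Columns: m value and
its SE (kcal mol^-1 M^-1), observed transition midpoint (M), dG0 and its
SE (kcal/mol), predicted (FoldX) and experimental ddG vs WT (kcal/mol).
These parameter pairs seed the synthetic round-trip checks and the demo
pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_fits"]


def load_reference_fits() -> pd.DataFrame:
    with resources.files("stabscan.data").joinpath(
        "arlbd_reference_fits.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
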
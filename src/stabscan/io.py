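"""Reading and writing the package's file formats.

Curves travel as per-sample CSV with header ``concentration_M,ellipticity``;
fits are written as JSON, audit tables as TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .denaturation import DenaturationCurve, TwoStateFit

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "fit_to_dict",
    "write_fit_json",
    "write_audit_tsv",
]

CURVE_COLUMNS = ("concentration_M", "ellipticity")


def read_curve_csv(path: str | Path, sample_id: str | None = None) -> DenaturationCurve:
    """Read one denaturation curve from CSV.

    The sample id defaults to the file stem. Points are sorted by
    concentration on read.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df.sort_values("concentration_M")
    return DenaturationCurve(
        sample_id=sample_id or path.stem,
        concentrations=tuple(df["concentration_M"].astype(float)),
        ellipticities=tuple(df["ellipticity"].astype(float)),
    )


def write_curve_csv(curve: DenaturationCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "concentration_M": curve.concentrations,
            "ellipticity": curve.ellipticities,
        }
    ).to_csv(path, index=False)
    return path


def fit_to_dict(fit: TwoStateFit) -> dict:
    return dataclasses.asdict(fit)


def write_fit_json(fit: TwoStateFit, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fit_to_dict(fit), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_audit_tsv(audit: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    audit.to_csv(path, sep="\t", index=False)
    return path
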
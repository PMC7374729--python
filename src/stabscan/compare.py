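"""Class-wise comparison of predicted folding-stability changes (ddG).

Ingests FoldX "Dif" output (tab-separated energy differences per mutant),
joins the predictions onto a classified variant catalog and contrasts
variant classes (disease vs polymorphism, CAIS vs PAIS, ...) with a
two-sample test. Positive ddG = destabilizing throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import VariantRecord
from .constants import DDG_THRESHOLD_DEFAULT
from .errors import InsufficientDataError, ParseError

__all__ = [
    "DdgRecord",
    "GroupComparison",
    "parse_foldx_dif",
    "join_ddg",
    "compare_groups",
    "classify_destabilizing",
    "strip_plot",
]


@dataclass(frozen=True)
class DdgRecord:
    """Predicted ddG (kcal/mol) for one single-residue variant.

    Replicate prediction runs for the same mutation are aggregated by
    mean; ``n_replicates`` records how many rows went in.
    """

    position: int
    ref_aa: str
    alt_aa: str
    ddg_pred: float
    n_replicates: int = 1
    source_file: str = ""

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)


#: Mutation code embedded in the first column of a Dif row, e.g. "I738T"
#: possibly decorated as "IA738T_1.pdb" (FoldX inserts a chain letter after
#: the wild-type residue and appends a run index / extension).
_MUT_RE = re.compile(r"([A-Z])([A-Z]?)(\d+)([A-Z])")


def _parse_mutation_tag(tag: str) -> tuple[int, str, str]:
    stem = tag.split(".")[0]
    m = _MUT_RE.search(stem)
    if not m:
        raise ParseError(f"cannot find a mutation code in tag {tag!r}")
    ref, _chain, pos, alt = m.groups()
    return int(pos), ref, alt


def parse_foldx_dif(path: str | Path) -> list[DdgRecord]:
    """Parse a FoldX "Dif" style tab-separated file into ddG records.

    The dialect: any number of preamble lines (blank, ``#`` comments, or a
    header whose second field is not numeric), then one row per prediction
    run with the mutant tag in the first tab-separated column and the total
    energy difference (kcal/mol) in the second. Replicate rows for the same
    mutation are averaged.
    """
    path = Path(path)
    runs: dict[tuple[int, str, str], list[float]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            try:
                value = float(fields[1])
            except ValueError:
                continue  # header / preamble line
            try:
                key = _parse_mutation_tag(fields[0])
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            runs.setdefault(key, []).append(value)
    if not runs:
        raise ParseError(f"{path}: no ddG rows found (preamble only?)")
    return [
        DdgRecord(
            position=pos,
            ref_aa=ref,
            alt_aa=alt,
            ddg_pred=float(np.mean(vals)),
            n_replicates=len(vals),
            source_file=str(path),
        )
        for (pos, ref, alt), vals in sorted(runs.items())
    ]


def join_ddg(
    catalog: Sequence[VariantRecord],
    ddg_records: Sequence[DdgRecord],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join predictions onto the catalog by (position, ref, alt).

    Returns the joined table (one row per matched prediction, with the
    variant's sources and phenotype) and an accounting dict whose values
    ``joined + unmatched + duplicate`` sum to ``len(ddg_records)``.
    """
    by_key: dict[tuple, VariantRecord] = {}
    for rec in catalog:
        by_key.setdefault(rec.key, rec)

    rows = []
    seen: set[tuple] = set()
    accounting = {"joined": 0, "unmatched": 0, "duplicate": 0}
    for d in ddg_records:
        if d.key in seen:
            accounting["duplicate"] += 1
            continue
        seen.add(d.key)
        rec = by_key.get(d.key)
        if rec is None:
            accounting["unmatched"] += 1
            continue
        accounting["joined"] += 1
        rows.append(
            {
                "position": d.position,
                "ref_aa": d.ref_aa,
                "alt_aa": d.alt_aa,
                "variant": str(rec),
                "ddg_pred": d.ddg_pred,
                "n_replicates": d.n_replicates,
                "phenotype": rec.phenotype,
                "sources": ";".join(sorted(rec.sources)),
            }
        )
    joined = pd.DataFrame(
        rows,
        columns=[
            "position", "ref_aa", "alt_aa", "variant", "ddg_pred",
            "n_replicates", "phenotype", "sources",
        ],
    )
    assert sum(accounting.values()) == len(ddg_records)
    return joined, accounting


@dataclass(frozen=True)
class GroupComparison:
    """A two-class contrast of ddG values."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    test_statistic: float
    p_value: float
    test_name: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    method: str = "welch",
) -> GroupComparison:
    """Two-sided two-sample test on ddG values.

    ``method`` is ``"welch"`` (default; unequal-variance t-test),
    ``"student"`` (pooled variance) or ``"mannwhitney"``. The groups
    compared here come from different variant sets of different sizes, so
    an unpaired test is the only coherent choice.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 values per group, got {a.size} ({label_a}) "
            f"and {b.size} ({label_b})"
        )
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "Welch t-test (two-sided)"
    elif method == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
        name = "Student t-test (two-sided)"
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U (two-sided)"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        test_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=name,
    )


def compare_by_column(
    joined: pd.DataFrame,
    column: str,
    class_a: str,
    class_b: str,
    method: str = "welch",
    value_column: str = "ddg_pred",
) -> GroupComparison:
    """Contrast two classes of a joined catalog/ddG table.

    For the ``sources`` column a row belongs to a class when the class tag
    appears in its (semicolon-joined) source set; for any other column an
    exact match is required.
    """
    if column == "sources":
        in_a = joined[column].str.split(";").apply(lambda s: class_a in s)
        in_b = joined[column].str.split(";").apply(lambda s: class_b in s)
    else:
        in_a = joined[column] == class_a
        in_b = joined[column] == class_b
    return compare_groups(
        joined.loc[in_a, value_column],
        joined.loc[in_b, value_column],
        label_a=class_a,
        label_b=class_b,
        method=method,
    )


def classify_destabilizing(
    ddg_pred: float, threshold: float = DDG_THRESHOLD_DEFAULT
) -> str:
    """Label a predicted ddG as stabilizing / neutral / destabilizing.

    Cutoffs are symmetric: ddG >= +threshold is destabilizing,
    ddG <= -threshold stabilizing, anything between is neutral.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ddg_pred >= threshold:
        return "destabilizing"
    if ddg_pred <= -threshold:
        return "stabilizing"
    return "neutral"


def strip_plot(
    joined: pd.DataFrame,
    group_column: str,
    out_path: str | Path,
    value_column: str = "ddg_pred",
    order: Sequence[str] | None = None,
    seed: int = 0,
) -> Path:
    """Grouped strip plot of ddG by class, saved to PNG/SVG.

    A jittered scatter with group means marked; matplotlib is imported
    lazily so headless analysis paths never touch it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = order or sorted(joined[group_column].dropna().unique())
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(1.8 * max(len(groups), 2) + 1, 4))
    for i, g in enumerate(groups):
        vals = joined.loc[joined[group_column] == g, value_column].to_numpy()
        x = i + rng.uniform(-0.18, 0.18, size=vals.size)
        ax.plot(x, vals, "o", ms=4, alpha=0.5)
        if vals.size:
            ax.hlines(vals.mean(), i - 0.3, i + 0.3, color="k", lw=2)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(r"predicted $\Delta\Delta G$ (kcal/mol)")
    ax.set_xlabel(group_column)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
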
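"""Synthetic data generators: denaturation curves and variant catalogs.

The curve generator inverts the two-state LEM chain — it draws the
sigmoid that the analysis is supposed to recover — so analysis of a
noiseless simulated curve is an exact round trip on (dG0, m). The catalog
generator emulates three overlapping single-residue-variant sets (an
inherited-disease set, a somatic/cancer set and a benign polymorphism
set) with class-specific ddG distributions, mirroring the structure of
HGMD / COSMIC / 1000-Genomes extracts for the androgen receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AMINO_ACIDS, AR_LENGTH, VariantRecord
from .compare import DdgRecord
from .constants import R_KCAL, T_DEFAULT
from .denaturation import DenaturationCurve

__all__ = [
    "CurveSpec",
    "simulate_curve",
    "two_state_theta",
    "ClassSpec",
    "CatalogSpec",
    "simulate_catalogs",
    "DEFAULT_CATALOG_SPEC",
]


def _default_grid() -> tuple[float, ...]:
    # 0-5 M in 0.25 M steps: 21 points spanning the full unfolding range.
    return tuple(np.round(np.arange(0.0, 5.0 + 1e-9, 0.25), 6))


@dataclass(frozen=True)
class CurveSpec:
    """Ground-truth parameters of a simulated two-state denaturation curve.

    ``dg0`` (kcal/mol, negative for a stable protein) and ``m_value``
    (kcal mol^-1 M^-1, positive) define the free-energy line; the thetas
    are the folded/unfolded ellipticity baselines in instrument units;
    ``noise_sd`` is the SD of homoscedastic Gaussian noise added to the
    ellipticities.
    """

    dg0: float
    m_value: float
    theta_folded: float = -20.0
    theta_unfolded: float = -5.0
    grid: tuple[float, ...] = field(default_factory=_default_grid)
    noise_sd: float = 0.0
    seed: int = 0
    sample_id: str = "sim"
    temperature_K: float = T_DEFAULT
    gas_constant: float = R_KCAL

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.size < 10:
            raise ValueError("concentration grid needs >= 10 points")
        if g.min() < 0 or g.max() > 6:
            raise ValueError("grid must lie within [0, 6] M")
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "grid", tuple(float(c) for c in g))


def two_state_theta(
    conc: np.ndarray,
    dg0: float,
    m_value: float,
    theta_folded: float,
    theta_unfolded: float,
    temperature_K: float = T_DEFAULT,
    gas_constant: float = R_KCAL,
) -> np.ndarray:
    """Noiseless two-state ellipticity: the forward model of the LEM chain.

    dG(c) = dg0 + m c; K = exp(-dG/RT); alpha = K/(1+K);
    theta = theta_U + alpha (theta_F - theta_U).
    """
    dg = dg0 + m_value * np.asarray(conc, dtype=float)
    k = np.exp(-dg / (gas_constant * temperature_K))
    alpha = k / (1.0 + k)
    return theta_unfolded + alpha * (theta_folded - theta_unfolded)


def simulate_curve(spec: CurveSpec) -> DenaturationCurve:
    """Draw one denaturation curve; deterministic given ``spec.seed``."""
    conc = np.asarray(spec.grid)
    theta = two_state_theta(
        conc,
        spec.dg0,
        spec.m_value,
        spec.theta_folded,
        spec.theta_unfolded,
        temperature_K=spec.temperature_K,
        gas_constant=spec.gas_constant,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        theta = theta + rng.normal(0.0, spec.noise_sd, size=theta.size)
    return DenaturationCurve(
        sample_id=spec.sample_id,
        concentrations=tuple(conc),
        ellipticities=tuple(float(t) for t in theta),
    )


# ---------------------------------------------------------------------------
# variant catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """One variant class: its size, ddG distribution and phenotype mix.

    ``ddg_mean``/``ddg_sd`` parametrize a normal truncated below at
    ``ddg_min``; ``phenotype_mix`` maps phenotype labels to sampling
    weights.
    """

    n_variants: int
    ddg_mean: float
    ddg_sd: float
    ddg_min: float = -1.0
    phenotype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"unknown": 1.0}
    )

    def __post_init__(self):
        if self.n_variants < 0:
            raise ValueError("class size must be >= 0")
        if self.ddg_sd <= 0:
            raise ValueError("ddg_sd must be positive")


@dataclass(frozen=True)
class CatalogSpec:
    """Three overlapping variant sets with class-specific ddG distributions.

    ``overlaps`` gives the number of variants shared by exactly the named
    pair (beyond the triple overlap) and by all three sets. Positions are
    drawn within ``position_intervals`` (default: the structured DBD and
    LBD, the only domains a structure-based ddG predictor can score).
    """

    disease: ClassSpec
    somatic: ClassSpec
    polymorphism: ClassSpec
    overlap_disease_somatic: int = 0
    overlap_disease_polymorphism: int = 0
    overlap_somatic_polymorphism: int = 0
    overlap_triple: int = 0
    position_intervals: tuple[tuple[int, int], ...] = ((560, 620), (691, 920))
    seed: int = 0

    def __post_init__(self):
        for lo, hi in self.position_intervals:
            if not (1 <= lo <= hi <= AR_LENGTH):
                raise ValueError(f"bad position interval [{lo}, {hi}]")
        sizes = {
            "disease": self.disease.n_variants,
            "somatic": self.somatic.n_variants,
            "polymorphism": self.polymorphism.n_variants,
        }
        shared = {
            "disease": self.overlap_disease_somatic
            + self.overlap_disease_polymorphism + self.overlap_triple,
            "somatic": self.overlap_disease_somatic
            + self.overlap_somatic_polymorphism + self.overlap_triple,
            "polymorphism": self.overlap_disease_polymorphism
            + self.overlap_somatic_polymorphism + self.overlap_triple,
        }
        for name in sizes:
            if shared[name] > sizes[name]:
                raise ValueError(
                    f"infeasible overlaps: class '{name}' holds {sizes[name]} "
                    f"variants but {shared[name]} are requested as shared"
                )


#: Defaults emulate the study conditions: 337 inherited-disease variants,
#: 323 somatic (cancer) variants, 39 benign polymorphisms. Disease ddG is
#: centered above 2 kcal/mol, polymorphisms around 1 kcal/mol and somatic
#: variants slightly below the polymorphisms.
DEFAULT_CATALOG_SPEC = CatalogSpec(
    disease=ClassSpec(
        n_variants=337, ddg_mean=2.5, ddg_sd=1.5,
        phenotype_mix={"CAIS": 0.40, "PAIS": 0.45, "MAIS": 0.10, "POF": 0.05},
    ),
    somatic=ClassSpec(
        n_variants=323, ddg_mean=0.8, ddg_sd=1.0,
        phenotype_mix={"prostate_cancer": 1.0},
    ),
    polymorphism=ClassSpec(
        n_variants=39, ddg_mean=1.0, ddg_sd=0.8,
        phenotype_mix={"none": 1.0},
    ),
    overlap_disease_somatic=25,
    overlap_disease_polymorphism=5,
    overlap_somatic_polymorphism=5,
    overlap_triple=2,
)

_CLASS_SOURCE_TAGS = {
    "disease": "HGMD",
    "somatic": "COSMIC",
    "polymorphism": "polymorphism",
}


def _truncated_normal(rng, mean, sd, lower, size):
    # rejection sampling; the truncation point sits far in the left tail
    # for all default classes, so this converges immediately
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[draw >= lower]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _draw_unique_variants(rng, n, intervals):
    """n distinct (position, ref, alt) keys uniform over the intervals.

    Each position gets one fixed reference residue (a real protein has a
    single wild-type sequence), so variants at the same position share ref.
    """
    positions = np.concatenate(
        [np.arange(lo, hi + 1) for lo, hi in intervals]
    )
    aas = sorted(AMINO_ACIDS)
    ref_of = {int(p): str(rng.choice(aas)) for p in positions}
    seen: set[tuple[int, str, str]] = set()
    keys: list[tuple[int, str, str]] = []
    while len(keys) < n:
        pos = int(rng.choice(positions))
        ref = ref_of[pos]
        alt = str(rng.choice([a for a in aas if a != ref]))
        key = (pos, ref, alt)
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys


def simulate_catalogs(
    spec: CatalogSpec = DEFAULT_CATALOG_SPEC,
) -> tuple[dict[str, list[VariantRecord]], list[DdgRecord]]:
    """Generate the three catalogs plus one ddG table.

    Returns ``(catalogs, ddg_records)`` where ``catalogs`` maps
    ``disease`` / ``somatic`` / ``polymorphism`` to variant lists of
    exactly the requested sizes, sharing exactly the requested overlap
    counts, and ``ddg_records`` holds one predicted ddG per unique variant
    (drawn from the distribution of its highest-priority class:
    disease > somatic > polymorphism). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    class_specs = {
        "disease": spec.disease,
        "somatic": spec.somatic,
        "polymorphism": spec.polymorphism,
    }
    region_sizes = {
        ("disease", "somatic", "polymorphism"): spec.overlap_triple,
        ("disease", "somatic"): spec.overlap_disease_somatic,
        ("disease", "polymorphism"): spec.overlap_disease_polymorphism,
        ("somatic", "polymorphism"): spec.overlap_somatic_polymorphism,
    }
    exclusive = {}
    for name, cs in class_specs.items():
        shared = sum(n for region, n in region_sizes.items() if name in region)
        exclusive[name] = cs.n_variants - shared
    for name in class_specs:
        region_sizes[(name,)] = exclusive[name]

    n_unique = sum(region_sizes.values())
    keys = _draw_unique_variants(rng, n_unique, spec.position_intervals)

    # deal unique keys out to regions, then assemble per-class memberships
    membership: dict[tuple[int, str, str], tuple[str, ...]] = {}
    i = 0
    for region in sorted(region_sizes, key=len, reverse=True):
        for _ in range(region_sizes[region]):
            membership[keys[i]] = region
            i += 1

    priority = ("disease", "somatic", "polymorphism")
    catalogs: dict[str, list[VariantRecord]] = {n: [] for n in class_specs}
    ddg_records: list[DdgRecord] = []
    for key, region in membership.items():
        pos, ref, alt = key
        lead = next(n for n in priority if n in region)
        cs = class_specs[lead]
        ddg = float(
            _truncated_normal(rng, cs.ddg_mean, cs.ddg_sd, cs.ddg_min, 1)[0]
        )
        ddg_records.append(
            DdgRecord(position=pos, ref_aa=ref, alt_aa=alt,
                      ddg_pred=ddg, n_replicates=1, source_file="simulated")
        )
        sources = frozenset(_CLASS_SOURCE_TAGS[n] for n in region)
        for name in region:
            mix = class_specs[name].phenotype_mix
            labels = sorted(mix)
            weights = np.array([mix[l] for l in labels], dtype=float)
            weights = weights / weights.sum()
            phenotype = str(rng.choice(labels, p=weights))
            catalogs[name].append(
                VariantRecord(
                    position=pos, ref_aa=ref, alt_aa=alt,
                    mutation_class="missense",
                    sources=sources, phenotype=phenotype,
                )
            )
    return catalogs, ddg_records


def catalogs_to_frame(catalogs: Mapping[str, Sequence[VariantRecord]]) -> pd.DataFrame:
    """Flatten simulated catalogs to the variant-table schema the parser reads."""
    rows = []
    for name, records in catalogs.items():
        for rec in records:
            rows.append(
                {
                    "position": rec.position,
                    "ref_aa": rec.ref_aa,
                    "alt_aa": rec.alt_aa,
                    "source": ";".join(sorted(rec.sources)),
                    "phenotype": rec.phenotype,
                    "dataset": name,
                }
            )
    return pd.DataFrame(rows)
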
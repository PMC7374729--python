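"""Two-state analysis of chemical (GdmHCl) denaturation curves.

The analysis follows the linear extrapolation method (LEM) for a monomeric
two-state (folded <-> unfolded) equilibrium monitored by CD ellipticity at
222 nm:

1. folded fraction      alpha_i = (theta_i - theta_U) / (theta_F - theta_U)
2. folding constant     K_i     = alpha_i / (1 - alpha_i)
3. point free energy    dG_i    = -R T ln K_i          (kcal/mol)
4. linear extrapolation dG_i    = dG0 + m [GdmHCl]

The intercept dG0 is the folding free energy at zero denaturant (negative
for a stable protein), the slope m (kcal mol^-1 M^-1) measures sensitivity
to denaturant, and the midpoint C_1/2 = -dG0/m is the concentration at
which half the population is unfolded.

Each transformation is exposed as its own function so the per-point chain
can be audited; :func:`analyze_curve` composes them end to end and returns
the fit together with a per-point audit table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    ALPHA_MAX_DEFAULT,
    ALPHA_MIN_DEFAULT,
    FOLDED_BASELINE_MAX_CONC,
    R_KCAL,
    T_DEFAULT,
    UNFOLDED_BASELINE_MIN_CONC,
)
from .errors import (
    DegenerateBaselineError,
    DomainError,
    InsufficientDataError,
    NoTransitionDataError,
    StageError,
)

__all__ = [
    "DenaturationCurve",
    "Baselines",
    "FractionSeries",
    "FreeEnergySeries",
    "TwoStateFit",
    "StabilityDelta",
    "FitConfig",
    "estimate_baselines",
    "folded_fraction",
    "folding_constant",
    "free_energy",
    "fit_lem",
    "ddg_relative",
    "analyze_curve",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenaturationCurve:
    """One denaturation experiment: ellipticity vs denaturant concentration.

    Parameters
    ----------
    sample_id
        Label for the protein sample (e.g. ``"WT"`` or ``"W752R"``).
    concentrations
        GdmHCl molarities, non-negative and strictly increasing.
    ellipticities
        CD ellipticity at 222 nm, arbitrary instrument units, one value
        per concentration.
    """

    sample_id: str
    concentrations: tuple[float, ...]
    ellipticities: tuple[float, ...]

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        ell = np.asarray(self.ellipticities, dtype=float)
        if conc.ndim != 1 or ell.ndim != 1:
            raise ValueError("concentrations and ellipticities must be 1-D")
        if len(conc) != len(ell):
            raise ValueError(
                f"length mismatch: {len(conc)} concentrations vs "
                f"{len(ell)} ellipticities"
            )
        if len(conc) < 5:
            raise ValueError("a denaturation curve needs at least 5 points")
        if np.any(conc < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", tuple(float(c) for c in conc))
        object.__setattr__(self, "ellipticities", tuple(float(e) for e in ell))

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class Baselines:
    """Ellipticity of the fully folded and fully unfolded states."""

    theta_folded: float
    theta_unfolded: float

    def __post_init__(self):
        if self.theta_folded == self.theta_unfolded:
            raise DegenerateBaselineError(
                "folded and unfolded baselines are identical "
                f"({self.theta_folded}); folded fraction is undefined"
            )


@dataclass(frozen=True)
class FractionSeries:
    """Folded fraction alpha per point, with retention flags.

    Points whose alpha falls outside the configured retention window are
    flagged ``retained=False`` rather than dropped, so the audit table can
    account for every input point.
    """

    sample_id: str
    concentrations: tuple[float, ...]
    fractions: tuple[float, ...]
    retained: tuple[bool, ...]

    def retained_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        mask = np.asarray(self.retained, dtype=bool)
        return (
            np.asarray(self.concentrations)[mask],
            np.asarray(self.fractions)[mask],
        )


@dataclass(frozen=True)
class FreeEnergySeries:
    """Point-wise folding constants and free energies on retained points."""

    sample_id: str
    concentrations: tuple[float, ...]
    folding_constants: tuple[float, ...]
    free_energies: tuple[float, ...] = ()
    gas_constant: float = R_KCAL
    temperature: float = T_DEFAULT


@dataclass(frozen=True)
class TwoStateFit:
    """Result of the linear extrapolation fit for one sample.

    ``c_half`` is always the derived midpoint ``-dg0 / m_value``; an
    independently observed midpoint, if any, travels in ``c_half_observed``.
    """

    sample_id: str
    dg0: float
    m_value: float
    c_half: float
    dg0_se: float
    m_se: float
    n_points_used: int
    r_squared: float
    c_half_observed: float | None = None
    noncooperative: bool = False

    def dg_at(self, concentration: float) -> float:
        """Evaluate the fitted line dG(c) = dg0 + m * c."""
        return self.dg0 + self.m_value * concentration


@dataclass(frozen=True)
class StabilityDelta:
    """Experimental ddG of a mutant relative to a reference sample.

    Positive values mean the mutant is less stable (destabilized), the
    same sign convention FoldX uses for predicted ddG.
    """

    mutant_id: str
    reference_id: str
    ddg_experimental: float


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the curve analysis.

    With ``theta_folded``/``theta_unfolded`` left as ``None`` the baselines
    are estimated from the curve itself: the folded baseline as the mean
    ellipticity of points at <= ``folded_max_conc`` M and the unfolded
    baseline as the mean at >= ``unfolded_min_conc`` M (5 M GdmHCl is
    assumed fully unfolding). Supply both to override.
    """

    theta_folded: float | None = None
    theta_unfolded: float | None = None
    alpha_min: float = ALPHA_MIN_DEFAULT
    alpha_max: float = ALPHA_MAX_DEFAULT
    temperature_K: float = T_DEFAULT
    gas_constant: float = R_KCAL
    folded_max_conc: float = FOLDED_BASELINE_MAX_CONC
    unfolded_min_conc: float = UNFOLDED_BASELINE_MIN_CONC

    def __post_init__(self):
        if not (0.0 <= self.alpha_min < self.alpha_max <= 1.0):
            raise ValueError("need 0 <= alpha_min < alpha_max <= 1")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.gas_constant <= 0:
            raise ValueError("gas constant must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def estimate_baselines(curve: DenaturationCurve, config: FitConfig | None = None) -> Baselines:
    """Estimate folded/unfolded baselines from the curve's flat regions."""
    config = config or FitConfig()
    conc = np.asarray(curve.concentrations)
    ell = np.asarray(curve.ellipticities)
    folded_pts = ell[conc <= config.folded_max_conc]
    unfolded_pts = ell[conc >= config.unfolded_min_conc]
    if folded_pts.size == 0:
        raise InsufficientDataError(
            f"no points at <= {config.folded_max_conc} M to estimate the folded baseline"
        )
    if unfolded_pts.size == 0:
        raise InsufficientDataError(
            f"no points at >= {config.unfolded_min_conc} M to estimate the unfolded baseline"
        )
    return Baselines(float(folded_pts.mean()), float(unfolded_pts.mean()))


def _longest_run(mask: np.ndarray) -> np.ndarray:
    """Keep only the longest contiguous True run (first on ties).

    A monotone two-state transition occupies a single contiguous
    concentration interval, so in-window points outside that interval are
    isolated noise excursions from the baselines and are excluded.
    """
    best_start, best_len = 0, 0
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    out = np.zeros_like(mask, dtype=bool)
    out[best_start : best_start + best_len] = True
    return out


def folded_fraction(
    curve: DenaturationCurve,
    baselines: Baselines,
    alpha_min: float = ALPHA_MIN_DEFAULT,
    alpha_max: float = ALPHA_MAX_DEFAULT,
) -> FractionSeries:
    """Normalize ellipticity to the folded fraction alpha per point.

    alpha_i = (theta_i - theta_U) / (theta_F - theta_U). Points outside
    [alpha_min, alpha_max] are flagged excluded (baseline regions carry no
    information about the transition and make ln K diverge), and retention
    is restricted to the longest contiguous in-window run so that isolated
    noise excursions from the flat baselines cannot masquerade as
    transition points.
    """
    theta = np.asarray(curve.ellipticities)
    span = baselines.theta_folded - baselines.theta_unfolded
    alpha = (theta - baselines.theta_unfolded) / span
    in_window = (alpha >= alpha_min) & (alpha <= alpha_max)
    retained = _longest_run(in_window)
    if not retained.any():
        raise NoTransitionDataError(
            f"sample '{curve.sample_id}': no points with folded fraction in "
            f"[{alpha_min}, {alpha_max}]; the curve shows no usable transition"
        )
    return FractionSeries(
        sample_id=curve.sample_id,
        concentrations=curve.concentrations,
        fractions=tuple(float(a) for a in alpha),
        retained=tuple(bool(r) for r in retained),
    )


def folding_constant(fractions: FractionSeries) -> FreeEnergySeries:
    """K_i = alpha_i / (1 - alpha_i) on the retained points."""
    conc, alpha = fractions.retained_arrays()
    bad = (alpha <= 0.0) | (alpha >= 1.0)
    if bad.any():
        i = int(np.argmax(bad))
        raise DomainError(
            f"sample '{fractions.sample_id}': retained point at "
            f"{conc[i]:g} M has folded fraction {alpha[i]:g}, outside (0, 1); "
            "the folding constant is undefined there"
        )
    k = alpha / (1.0 - alpha)
    return FreeEnergySeries(
        sample_id=fractions.sample_id,
        concentrations=tuple(float(c) for c in conc),
        folding_constants=tuple(float(v) for v in k),
    )


def free_energy(
    series: FreeEnergySeries,
    temperature_K: float = T_DEFAULT,
    gas_constant: float = R_KCAL,
) -> FreeEnergySeries:
    """dG_i = -R T ln K_i in kcal/mol."""
    if temperature_K <= 0:
        raise DomainError("temperature must be positive (kelvin)")
    k = np.asarray(series.folding_constants)
    if np.any(k <= 0):
        raise DomainError(
            f"sample '{series.sample_id}': non-positive folding constant"
        )
    dg = -gas_constant * temperature_K * np.log(k)
    return replace(
        series,
        free_energies=tuple(float(v) for v in dg),
        gas_constant=gas_constant,
        temperature=temperature_K,
    )


def fit_lem(series: FreeEnergySeries, min_conc_span: float = 0.2) -> TwoStateFit:
    """Ordinary least squares of dG_i on [GdmHCl]: the linear extrapolation.

    Intercept = dG0, slope = m, midpoint C_1/2 = -dG0/m. Standard errors
    come from the regression. A non-positive slope marks the fit
    non-cooperative (``noncooperative=True``) rather than raising.
    """
    c = np.asarray(series.concentrations, dtype=float)
    dg = np.asarray(series.free_energies, dtype=float)
    if dg.size != c.size or dg.size == 0:
        raise InsufficientDataError(
            f"sample '{series.sample_id}': free energies not computed"
        )
    if c.size < 3:
        raise InsufficientDataError(
            f"sample '{series.sample_id}': only {c.size} point(s) in the "
            "transition region; need at least 3 for the linear extrapolation"
        )
    span = float(c.max() - c.min())
    if span <= min_conc_span:
        raise InsufficientDataError(
            f"sample '{series.sample_id}': transition points span only "
            f"{span:g} M (> {min_conc_span} M required)"
        )
    res = stats.linregress(c, dg)
    dg0 = float(res.intercept)
    m = float(res.slope)
    c_half = -dg0 / m if m != 0 else float("nan")
    return TwoStateFit(
        sample_id=series.sample_id,
        dg0=dg0,
        m_value=m,
        c_half=float(c_half),
        dg0_se=float(res.intercept_stderr),
        m_se=float(res.stderr),
        n_points_used=int(c.size),
        r_squared=float(res.rvalue**2),
        noncooperative=m <= 0,
    )


def ddg_relative(mutant: TwoStateFit, reference: TwoStateFit) -> StabilityDelta:
    """Experimental ddG = dG0(mutant) - dG0(reference).

    Positive = destabilizing (the mutant's folding free energy is less
    negative than the reference's), matching the FoldX sign convention.
    """
    return StabilityDelta(
        mutant_id=mutant.sample_id,
        reference_id=reference.sample_id,
        ddg_experimental=mutant.dg0 - reference.dg0,
    )


def analyze_curve(
    curve: DenaturationCurve,
    config: FitConfig | None = None,
) -> tuple[TwoStateFit, pd.DataFrame]:
    """Run the full two-state LEM chain on one curve.

    Composes folded_fraction -> folding_constant -> free_energy -> fit_lem
    and returns the fit plus a per-point audit table with columns
    ``concentration_M, ellipticity, alpha, K, dG_kcal_mol, retained``
    (K and dG are NaN on excluded points).
    """
    config = config or FitConfig()
    try:
        if config.theta_folded is not None and config.theta_unfolded is not None:
            baselines = Baselines(config.theta_folded, config.theta_unfolded)
        elif config.theta_folded is None and config.theta_unfolded is None:
            baselines = estimate_baselines(curve, config)
        else:
            raise ValueError(
                "supply both theta_folded and theta_unfolded, or neither"
            )
        fractions = folded_fraction(
            curve, baselines, alpha_min=config.alpha_min, alpha_max=config.alpha_max
        )
    except Exception as exc:  # attach the stage name
        raise StageError("folded_fraction", exc) from exc

    try:
        kseries = folding_constant(fractions)
    except Exception as exc:
        raise StageError("folding_constant", exc) from exc
    try:
        gseries = free_energy(
            kseries, temperature_K=config.temperature_K, gas_constant=config.gas_constant
        )
    except Exception as exc:
        raise StageError("free_energy", exc) from exc
    try:
        fit = fit_lem(gseries)
    except Exception as exc:
        raise StageError("fit_lem", exc) from exc

    audit = pd.DataFrame(
        {
            "concentration_M": curve.concentrations,
            "ellipticity": curve.ellipticities,
            "alpha": fractions.fractions,
            "retained": fractions.retained,
        }
    )
    k_map = dict(zip(gseries.concentrations, gseries.folding_constants))
    g_map = dict(zip(gseries.concentrations, gseries.free_energies))
    audit["K"] = audit["concentration_M"].map(k_map)
    audit["dG_kcal_mol"] = audit["concentration_M"].map(g_map)
    audit = audit[
        ["concentration_M", "ellipticity", "alpha", "K", "dG_kcal_mol", "retained"]
    ]
    return fit, audit
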
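"""Physical constants and default analysis parameters.

All free energies in this package are in kcal/mol, denaturant
concentrations in mol/L (M), temperatures in kelvin.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Default absolute temperature (25 degC), matching typical CD conditions.
T_DEFAULT: float = 298.15

#: Default folded-fraction retention window for the linear extrapolation.
#: ln K diverges as alpha -> 0 or 1 and the propagated free-energy error
#: sigma_dG = R T sigma_alpha / (alpha (1 - alpha)) explodes near the
#: baselines, so only the central transition region is retained.
ALPHA_MIN_DEFAULT: float = 0.10
ALPHA_MAX_DEFAULT: float = 0.90

#: Baseline-estimation policy: the folded baseline is the mean ellipticity of
#: points at or below this concentration ...
FOLDED_BASELINE_MAX_CONC: float = 0.25
#: ... and the unfolded baseline the mean of points at or above this one
#: (GdmHCl at 5 M is taken to unfold the protein completely).
UNFOLDED_BASELINE_MIN_CONC: float = 5.0

#: |ddG| cutoff (kcal/mol) separating neutral from (de)stabilizing variants;
#: about 3 kcal/mol of destabilization is enough to route a protein into
#: quality-control degradation.
DDG_THRESHOLD_DEFAULT: float = 3.0
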
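# Methods

## Two-state linear extrapolation analysis

The denaturation analysis assumes a monomeric two-state equilibrium
F ⇌ U whose population is read out by CD ellipticity at 222 nm. Under
fixed (unsloped) pre- and post-transition baselines θ_F and θ_U, the
folded fraction at denaturant concentration c_i is

    α_i = (θ_i − θ_U) / (θ_F − θ_U),

the folding constant K_i = α_i/(1 − α_i), the point-wise folding free
energy ΔG_i = −RT ln K_i, and the linear extrapolation model posits
ΔG(c) = ΔG₀ + m·c, fitted by ordinary least squares of ΔG_i on c_i. The
procedure is deliberately the point-wise-then-linear composition, not a
global nonlinear fit of the sigmoid: each stage is exposed separately and
the per-point audit table (c, θ, α, K, ΔG, retained) makes the chain
checkable by eye.

Key assumptions: two states only (no intermediates, no dimerization),
linear ΔG–denaturant dependence over the observed range, ellipticity an
affine population readout (the α normalization cancels instrument scale
and sign, so raw instrument units are accepted as-is), and complete
unfolding at 5 M GdmHCl.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| R | 1.9872×10⁻³ | kcal·mol⁻¹·K⁻¹ | gas constant (kcal scale) |
| T | 298.15 | K | measurement temperature (25 °C) |
| α window | [0.10, 0.90] | — | transition-region retention |
| θ_F policy | mean of points ≤ 0.25 M | instrument units | folded baseline estimate |
| θ_U policy | mean of points ≥ 5 M | instrument units | unfolded baseline estimate |
| min points / span | 3 / 0.2 M | — | regression validity floor |
| ΔΔG cutoff | 3.0 | kcal/mol | neutral vs (de)stabilizing label |

Derived outputs: C₁/₂ = −ΔG₀/m is always reported as the derived value;
an independently observed midpoint can be carried alongside
(`c_half_observed`) but is never substituted into it. ΔΔG =
ΔG₀(mutant) − ΔG₀(reference), positive = destabilizing, the same sign
convention as FoldX predictions.

### Transition-region retention

Only points with α in [0.10, 0.90] enter the regression, and among those
only the longest contiguous run of in-window points is retained; all
exclusions are flagged in the audit table, never dropped. Two effects
motivate this choice. First, the propagated free-energy error
σ_ΔG = RT·σ_α/(α(1−α)) diverges toward the baselines, so near-baseline
points have enormous leverage on the intercept. Second, with noisy data a
point whose *true* α sits outside the window can be pulled inside by
noise; because inclusion is conditional on the noise draw, such points
enter with systematically biased ΔG (a selection/truncation effect). With
a wide window (e.g. [0.02, 0.98]) this bias reaches ~0.3 kcal/mol on ΔG₀
at 2%-of-span ellipticity noise; the central-region window plus
contiguity rule reduces it below 0.1 kcal/mol while leaving noiseless
analysis exact. Both window edges are configurable.

### Baselines

By default θ_U is the mean ellipticity of points at ≥ 5 M (full
unfolding assumed there) and θ_F the mean at ≤ 0.25 M; both can be
overridden explicitly, and must be overridden together. The low-c policy
is itself an approximation: a marginally stable protein (ΔG₀ around
−1 kcal/mol) is measurably unfolded even at 0 M, so its plateau mean
underestimates |θ_F|. For that reason the synthetic round-trip checks
pass the generator's true baselines to the analysis — they exercise the
equation chain, not the baseline heuristic. Sloped baselines and thermal
denaturation are out of scope (aggregation makes temperature ramps
unreliable for these samples).

### Degenerate inputs

Identical baselines raise a degenerate-baseline error; a curve whose
points all sit in a baseline region raises a no-transition-data error;
fewer than 3 retained points, or a retained span ≤ 0.2 M, raises an
insufficient-data error; a non-positive fitted slope is flagged
non-cooperative rather than raised, since the fitted numbers may still be
diagnostic. Pipeline wrappers attach the failing stage's name.

## Variant catalog

Positions follow the 920-aa NM_000044.2 protein (poly-Q 23 / poly-G 23);
a configurable integer offset supports legacy 919-aa coordinates. Domains
tile the protein: NTD 1–559, DBD 560–620, hinge 621–690, LBD 691–920.
The boundary residue 559 and the hinge interval are fixed here as a
design choice — published domain descriptions leave them open — and the
bipartite NLS (617–634) straddling the DBD/hinge border is kept as an
annotation, not a domain. Variant identity is (position, ref, alt);
dataset tags and phenotype are annotations on top. The parser never drops
rows silently: accepted + rejected = input rows, with per-row reasons.

## ΔΔG comparison

FoldX "Dif" files are consumed as tab-separated rows with the mutation
code in the first column and the total energy difference in the second;
replicate runs of the same mutation are averaged (recorded in
`n_replicates`). Running FoldX or any energy function is out of scope.

The class contrast defaults to Welch's unpaired two-sided t-test. A
paired test is not meaningful for groups of unequal size drawn from
different variant sets (e.g. 337 disease vs 39 polymorphism variants),
so pairing is not offered; pooled-variance Student and Mann–Whitney
alternatives are. Raw p-values are reported by default; a Bonferroni
factor can be applied externally for the three pairwise contrasts.
The ~3 kcal/mol destabilization threshold used for labelling reflects
the scale at which quality-control degradation of a destabilized protein
is triggered.

## Synthetic data generator

`simulate_curve` draws θ(c) from the exact forward model of the LEM chain
(ΔG = ΔG₀ + m·c, K = e^(−ΔG/RT), α = K/(1+K), θ = θ_U + α(θ_F − θ_U))
plus homoscedastic Gaussian ellipticity noise, on a 0–5 M grid in 0.25 M
steps by default. Real CD data differ in ways the generator does not
emulate: sloped baselines, heteroscedastic and correlated noise,
aggregation artifacts, incomplete unfolding at 5 M. Passing round-trip
tests therefore demonstrates correctness of the analysis chain, not
robustness to every experimental pathology.

A note on parameter ranges: a (ΔG₀, m) pair only yields an observable
transition if C₁/₂ = −ΔG₀/m lies on the concentration grid; pairs such
as (−8, 0.5) put the midpoint at 16 M and correctly fail with
no-transition-data. Randomized round-trip tests draw from the
physiological box ΔG₀ ∈ [−8, −1], m ∈ [0.5, 2.5] restricted to
−ΔG₀/m ≤ 4.3.

`simulate_catalogs` emulates three overlapping variant sets at the study
sizes (337 inherited-disease, 323 somatic, 39 polymorphism variants),
with positions confined to the structured DBD and LBD (the only domains
a structure-based ΔΔG predictor can score) and one fixed wild-type
residue per position. Class ΔΔG distributions are truncated normals
(truncation at −1 kcal/mol): disease N(2.5, 1.5) — disease-average above
2 kcal/mol; polymorphism N(1.0, 0.8) — centred near 1 kcal/mol; somatic
N(0.8, 1.0) — slightly below the polymorphisms. A variant in several
sets receives one ΔΔG, drawn from its highest-priority class (disease >
somatic > polymorphism). Overlap counts are exact by construction;
the defaults (disease∩somatic 25, disease∩polymorphism 5,
somatic∩polymorphism 5, triple 2) are the package's own choice of small
overlaps. Phenotypes within the disease class are sampled from a
CAIS 0.40 / PAIS 0.45 / MAIS 0.10 / POF 0.05 mix; the generator encodes
no CAIS-vs-PAIS difference in predicted ΔΔG, so that contrast is null on
synthetic data by design — the CAIS/PAIS stability ordering is carried by
the measured denaturation parameters instead. All randomness flows
through one explicit seed per spec; there is no global RNG state.

## Problem sizes and determinism

The statistical calibration check uses 1,000 simulated null comparisons
at n = 30 per group; round-trip checks use 20 random specs and 50 noisy
replicates — sizes at which the Monte-Carlo error is well inside the
asserted bands. Pipeline runs with identical config and seed are
byte-identical in their numerical outputs (no timestamps in summaries).

## Known limitations

* Fixed baselines only; no three-state or dimer unfolding models.
* The baseline-estimation heuristic biases α for marginally stable
  proteins (see above); supply measured baselines when available.
* Standard errors of ΔG₀ and m come from unweighted OLS and ignore
  α-dependent error propagation; for noiseless synthetic data they are
  exactly zero.
* Domain-level statistics on synthetic catalogs reflect the generator's
  uniform position model, not mutational hotspots of the real protein.
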
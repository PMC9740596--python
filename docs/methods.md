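# Methods

## The model

The model describes whole-body glucose/insulin/lipid exchange between
four compartments — liver (volume `alpha_L` = 1.6 L), skeletal muscle
(`alpha_M` = 26.4 L), adipose tissue (`alpha_A` = 15.6 L) and blood
plasma — through 23 coupled balance equations.  State variables are
plasma insulin `I` (pmol/L) and 22 concentrations in mmol/L: liver
glucose/G6P/glycogen/pyruvate/FFA and two TAG pools (secretory `S_L`,
storage `T_L`), their muscle analogues plus muscle AMP `P`, adipose
TAG/FFA/glycerol/glucose, and the plasma species chylomicron TAG
`T_CB`, NEFA `A_NB`, endogenous lipoprotein (VLDL) TAG `T_LB` and
glucose `G_B`.

Every balance is assembled from a registry of 45 named reaction fluxes
`v1 … v45`; each registry entry carries its rate law and the signed
stoichiometric factor with which it enters each balance (TAG↔FFA
conversions carry the factor 3 — three fatty acids per triglyceride).
Key laws:

* insulin secretion `v1 = k_11 + k_22·erf((G_B − v)/c_c)` — basal plus
  glucose-stimulated, with threshold `v` = 7 mmol/L and sensitivity
  range `c_c` = 2.5 mmol/L; degradation `v2 = k_d·I`;
* liver glycogen turnover `v9`: insulin-stimulated synthesis saturating
  at the capacity `l_max` through `(1 + tanh((l_max − Y_L)/c_0))/2`,
  minus insulin-inhibited glycogenolysis
  `beta_L/(1 + k_dl·I) · Y_L/(Y_L + y_0)`;
* VLDL secretion `v24 = F_I · v_9·T_L/(k_9 + T_L)` with the
  insulin-modified secretion fraction
  `F_I = k_12·tanh((v_12 − I)/k_13) + k_14`;
* Michaelis–Menten phosphorylation (glucokinase/hexokinase, the latter
  product-inhibited by `1/(1 + k_rep·P_L)`), first-order plasma
  transports, and insulin-gated adipose esterification/lipolysis.

A meal enters as a bolus: the meal-derived glucose and TAG set
`G_B(0)` and `T_LB(0)`; the dietary input fluxes `S_G(t)`, `S_F(t)` are
zero afterwards (an exponential forcing mode exists for completeness).

### Documented corrections and conventions

The published constant table and balance list contain internal
inconsistencies; every interpretation is recorded in the parameter
provenance log and summarised here.

* `k_dl` printed as `3.5 × 18^8` → 3.5 × 10⁸ (mantissa/base typo).
* The P_L-side glycogenolysis denominator printed `1 + k_p6·I` is read
  as `1 + k_dl·I` (matching the Y_L side and `k_dl`'s documented role),
  and the A_L-side esterification denominator printed `1 + k_5·I` is
  read as the Michaelis form `k_8 + A_L` (matching the T_L side), so
  each process is a single mass-consistent flux.
* The plasma-NEFA balance is completed from its documented reaction
  list: `+3·beta_f/(1 + k_ft·I²) + 3·k_a·(1 + k_ai·I)·T_CB`.
* The plasma–adipose glucose exchange uses the conservative difference
  form `d_ba·(1 + k_ga·I)·(G_B − G_A)` in both balances; the printed
  product form is available behind `adipose_glucose_product=True`.
* Muscle and adipose balances are divided by their own compartment
  volumes; the literal table (which shows `alpha_L` everywhere) is
  available behind `uniform_liver_volume=True`.
* `mu_b` enters the liver pyruvate balance twice as printed (factor 2).
* One constant (`beta_G`) appears in the published sensitivity-figure
  row lists but has no recoverable value and enters no balance; it is
  carried as an inert parameter (nominal 1.0) so the varied set counts
  78.  `mu_s`, `mu_e` and `k_lp` likewise appear in no balance (the
  muscle TAG terms use `m_s`, `m_e` as printed) and are inert but
  varied.
* Physiologically implausible magnitudes are implemented exactly as
  documented — most prominently `k_d` = 1.733 × 10¹⁴, which forces
  insulin onto the quasi-steady manifold `I ≈ v1(G_B)/k_d ~ 10⁻¹³`
  pmol/L within ~10⁻¹⁴ min.  `units_report()` enumerates the known
  dimensional mismatches; they are flagged, not repaired.  A
  `ParameterSet.replace()` override mechanism supports alternative
  values without code changes.

## Menu conversion

Energy fractions use Atwater factors 4/9/4 kcal/g; they reproduce all
the documented daily percentages of the four packaged menus exactly at
one-decimal rounding (half-up).  Initial plasma glucose is
`carb_g / 1.80` (glucose molar mass 0.180 g/mmol × 10 L distribution
volume), which reproduces all 16 reference values exactly at one
decimal.  No clean molar-mass/volume constant reproduces the TAG grid,
so the fat factor is fitted by origin-constrained least squares of
grams on concentration over the 16 reference pairs (3.585 g per
mmol/L); leave-one-out predictions stay within 0.1 mmol/L of every
reference value.  The menus print no protein grams; protein is the
Atwater residual `(kcal − 4·carb − 9·fat)/4`, so fractions close at
100% by construction.  Saturated-fat grams are metadata.

The synthetic-menu generator draws daily energy uniformly in
2000 ± 100 kcal, a carbohydrate energy fraction in [0.05, 0.60] and a
fat fraction in [0.20, 0.80] (truncated so protein keeps ≥ 3% of
energy), splits energy over breakfast/lunch/snack/dinner with the
empirical energy shares of the packaged menus, and converts to grams
with the same Atwater factors.  It emulates the macronutrient structure
of realistic one-day menus — ketogenic through high-carbohydrate — but
not food identity, micronutrients, meal timing or day-to-day
correlation; passing tests therefore certify the conversion and
sensitivity machinery over this composition range, not dietary realism.

## Integration

The printed constants span ~20 orders of magnitude, so all integration
is stiff-capable.  Single trajectories use LSODA at `rtol 1e-8`,
`atol 1e-10` with dense output; two other implicit methods (BDF, Radau)
agree within 0.5% and a tenfold tolerance tightening moves no state by
more than 0.1% (enforced by tests).  The Jacobian is analytic,
generated by sympy from the same symbolic source as the SBML export —
finite-difference Jacobians misbehave on the insulin quasi-steady
manifold, where the absolute tolerance exceeds `I` itself by orders of
magnitude.  Concentrations are never clamped; negative excursions are
reported as diagnostics because clamping would silently change the
model being analysed.

The 2000-sample screening runs use the same LSODA core at `rtol 1e-6`,
`atol 1e-9` with `mxstep = 2500` as a fast-fail bound (successful draws
need ≈ 1200 steps).  The model has a genuine finite-time pole: `P_L`
can drift negative until the hexokinase inhibition factor
`1/(1 + k_rep·P_L)` diverges at `P_L = −1/k_rep`.  Under the two-decade
log span roughly 40% of draws hit it before 500 min.  Such draws are
replaced by the value of the nearest valid neighbour on the `s` grid
(zero-order, consistent with the method's interpolation rule), counted
and reported per run; a failure fraction above a configurable ceiling
(default 0.5) aborts the analysis.

## FAST design

Each varied constant oscillates along the search curve
`x_i(s) = 1/2 + arcsin(sin(pi·omega_i·s + phi_i))/pi`, `s ∈ [−1, 1]`
split into 2000 identical segments (midpoint sampling), a triangular
wave with uniform marginal on [0, 1].  Parameters are scaled
`p_i = nominal_i · 10^(span·(x_i − 1/2))` with a default span of two
decades (log-uniform over [nominal/10, 10·nominal]); the three
compartment volumes stay nominal.  With `theta = pi·s`, Fourier
coefficients `A_w, B_w` are rectangle-rule integrals of the zero-order
interpolated output; the total variance `D = 2·Σ(A_w² + B_w²)` is
truncated at the maximum analysis frequency (500), the partial variance
`D_i` sums the harmonics `p·omega_i ≤ 500`, and `S_i = D_i/D` (a
zero-variance output has all-zero indices by convention).

Truly incommensurate integer frequencies do not exist: 78 integers in
[5, 159] must contain pairs whose low-order harmonics coincide (the
largest divisibility-free subset of the band compatible with the
correlation filter has ~70 members).  The draw therefore proceeds in
layers:

* an odd-harmonic interference filter (including grid aliases, which
  fold with period 2000) rejects any pair whose worst-case x-column
  correlation contribution `~0.99/(p²q²)` exceeds 4 × 10⁻³ — without it
  ratio-3 pairs alone would correlate at the 0.1 level;
* a harmonic-comb filter rejects pairs where a low-order multiple of
  one frequency is divisible by the other; it is applied at the
  strongest feasible order (order 2 for small oracle designs; for 78
  parameters no positive order is feasible and the filter is waived);
* the empirical correlation matrix of the drawn columns is computed and
  the design redrawn until its maximum is ≤ 4 × 10⁻³.  Accepted
  78-parameter designs have a maximum pairwise correlation of
  ≈ 3.4 × 10⁻³ — an irreducible floor from aggregated high-order alias
  coincidences — with more than 99% of pairs below 10⁻³.

Because comb overlap cannot be eliminated at n = 78, two safeguards
apply: a spectral line that is another parameter's fundamental is
excluded from `D_i` (it carries that parameter's first-order
signature), and the residual over-attribution is quantified per run as
`epsilon = max(0, Σ S_i − 1)` and reported, never assumed away.  For
small designs (≤ 6 parameters) the draw additionally rejects low-order
linear combinations `Σ lambda_j·omega_j` that vanish or land on strong
attributed lines — the classical incommensurability condition — which
is what makes the Ishigami benchmark reproducible to ±0.02 at 2000
samples (the benchmark's variance sits at the fourth harmonic of its
second input under this search curve, so oracle tests use a band and
analysis window, (5, 125) and 900, that contain its spectrum).

## Non-stationary analysis

One integration per parameter sample, read from a single solve at
`t_f = 10, 50, 100, 250 and 500` min (one published passage says 200
min where every figure and the methods text say 250; 250 is used).
At each horizon every metabolite concentration and every registry
reaction rate becomes an output series over `s` and is decomposed as
above, giving 78 × 23 and 78 × 45 index matrices per horizon.  Exports
follow the published figure ordering; cells are colour-classed by
percentile within the matrix (green below the median; 50/75/90/97.5
breaks toward red — the finer breaks are a rendering choice), and
columns whose every entry exceeds the matrix median are flagged.

### What reproduces, and what depends on unpublished conventions

With the documented constants and the conditions above, the magnitude
landmarks of the analysis reproduce: the largest metabolite index
exceeds 0.80 under both lunch scenarios (0.837 ketogenic / 0.840
general-population at this package's reference seed) and the largest
reaction index for the general-population lunch is ≈ 0.998 against the
published 0.986.  The muscle glycogen and TAG pools dominate the
sensitive columns, matching the published call-outs.

The *identity* of the top parameters does not reproduce.  In this
implementation the maxima belong to muscle glycogenolysis (`beta_M`) on
`Y_M`, with liver glycogenolysis (`beta_L`) reaching 0.68–0.69, whereas
the source analysis reports `beta_L` and the basal insulin secretion
rate `k_11` above 0.80; and the storage-hydrolysis flux
`v19 = v_10·T_L/(k_10 + T_L)` is dominated — as its rate law dictates
when `T_L ≫ k_10` — by its own constant `v_10` (index ≈ 0.88), not by
the published triple `beta_L` (0.617), `k_a` (0.603), `beta_M` (0.157),
whose sum exceeds 1 and therefore already reflects design-specific
aliasing.  Three documented convention sweeps (one- vs two-decade span;
the literal uniform-`alpha_L` volume convention; a physiological
insulin clearance override `k_d = 0.0733`) do not restore the published
ranking.  The structural cause is the printed `k_d`: it reduces insulin
to ~10⁻¹³ pmol/L, which multiplied by the printed insulin-coupling
constants leaves every insulin-mediated pathway — the only route by
which `k_11` can influence the lipid pools — numerically inert.
Reproducing the published identities would require the source
analysis's undocumented unit conventions and its unpublished random
frequency/phase draw; the package implements the documented model and
reports what it computes.

## Known limitations

* Indices are first-order only; the large unattributed variance share
  (most propagated uncertainty is interactional) is visible as
  `1 − Σ S_i` per output but not decomposed further.
* ~40% of wide-span draws terminate at the model's pole and are imputed;
  the imputation preserves the zero-order interpolation convention but
  flattens `y(s)` over failed stretches, so indices under heavy failure
  should be read as screening-quality.
* The SBML export is structural (compartments, species, parameters,
  reactions with MathML rate laws) and validated for well-formedness
  and counts, not against an SBML validator.
* The bolus convention makes the two dietary input fluxes identically
  zero, so their sensitivity rows/columns are zero by the
  zero-variance convention.
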
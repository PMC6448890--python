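# Methods

## Model and assumptions

The package fits compression isotherms π(a_L) of insoluble lipid
monolayers with an equation of state in which the film is an open
two-dimensional solution of hydrated head groups exchanging water with
the subphase.  Linear irreversible thermodynamics couples the area flux
driven by surface pressure to the water flux driven by the chemical
potential of interfacial water, through four phenomenological mobility
coefficients: l_ww (water–water), l_LL (lipid–lipid friction) and the
cross terms l_wL, l_Lw.  At mechanical equilibrium the coupled fluxes
yield

    π = (k₁ + k₂) · κ(T)/a_L,   k₁ = l_ww/(l_LL + l_Lw),  k₂ = l_wL/(l_LL + l_Lw)

and, letting the cross coefficient vary with compression as a power law
l_wL ∝ (a₀/a_L)^m with reference area a₀, the working form

    π_p = k₁·κ(T)/a_L + k₂′·(κ(T)/a₀)·(a₀/a_L)^p,   p = m + 1 integer.

Assumptions inherited from the derivation: quasi-static compression (each
recorded point is an equilibrium), insoluble lipid (no desorption into
the subphase), a flat film (no collapse or curvature regime — the toolkit
is not meant for the post-collapse branch), and coefficients that are
constant *within* a phase region but differ between the liquid-expanded
(LE), LE/LC-coexistence and liquid-condensed (LC) regimes, which is why
fitting is piecewise.

Setting l_ww = l_LL and zero cross terms gives (k₁, k₂) = (1, 0) and the
ideal 2D gas πa_L = κ(T); the 2D van der Waals gas
π = κ/(a_L − b) − a/a_L² is retained as the classical baseline.

## Units

Areas are Å²/molecule, pressures mN/m, temperatures kelvin.  κ(T) = k_B·T
per molecule equals 1.380649·T in mN·Å²/m, so κ/a_L is directly mN/m.
The molar convention (R·T with molar areas) is numerically identical; the
per-molecule form matches how isotherms are reported.  The pure-water
surface tension default is γ₀ = 72 mN/m (25 °C).

## Fitting

For fixed integer p the model is linear in (k₁, k₂′) with basis
{κ/a_L, (κ/a₀)(a₀/a_L)^p}; each candidate p ∈ {1, …, 10} (configurable)
is solved by ordinary least squares and the p with minimal residual sum
of squares is kept.  Residual ties — compared after normalizing by the
squared data norm, at 10⁻¹² — break toward the smaller p for parsimony.
Coefficient standard errors come from the homoscedastic linear-model
covariance σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n − 2); the noise model is i.i.d.
Gaussian because trough exports carry no replicate error estimates.

**p = 1 degeneracy.**  At p = 1 the two basis functions coincide, so only
the sum k₁ + k₂′ is identifiable from data.  The fit then estimates the
single sum coefficient, reports it as k₁ with k₂′ = 0, attaches an
explanatory note, and its standard error refers to the sum.  A corollary:
on data generated with p = 1 every exponent fits equally well (k₂′ = 0
absorbs the model), so the selected p on a noisy coexistence plateau is
noise-determined while the fitted curve itself is stable.  Parameter
recovery statements for p = 1 regions therefore concern (p, k₁ + k₂′)
only.

**Region segmentation.**  Region membership is user-configured first
(half-open intervals [lo, hi) on a_L, top region closed at the data
maximum, every point in exactly one region, ≥ 3 points per region).  An
auto mode locates the coexistence plateau as the longest interior run of
central-difference slopes whose magnitude falls below a configurable
fraction (default 0.25) of the median slope magnitude; it is a
convenience heuristic flagged as such, not a claim about phase
boundaries, and it requires the plateau to be genuinely the flattest part
of the curve.

**van der Waals fit.**  Bounded nonlinear least squares
(scipy's trust-region reflective) with a_coh ≥ 0 and 0 ≤ b < min a_L,
Jacobian-scaled steps because the two parameters live three orders of
magnitude apart, deterministic for a given start (default the ideal-gas
corner (0, 0)).  Non-convergence is flagged on the result with the best
iterate retained.

**Error metrics.**  Pointwise E(a_L) = |π_exp − π_model| and the
integrated error E_int = ∫|π_exp − π_model| da_L normalized by the a_L
range width, so E_int is a range-averaged absolute error in mN/m and
directly comparable with E.  The normalization constant is a design
choice: it makes E_int independent of the sampled range width and puts
the pointwise and integrated panels on one scale.  Quadrature is
trapezoidal on the data grid.

## Transport coefficients

Recasting the mobilities as diffusivities gives
k₁ = D_ww/(D_LL + D_Lw) and k₂ = D_wL/(D_LL + D_Lw); inverting the fitted
coefficients for a region yields

    D⁰_Lw = (k₂′/|k₁|)·D_ww,      D⁰_wL = D_ww/|k₁| − D_LL.

Fitted k₁ values are negative in the condensed and coexistence regimes
while diffusivities are positive by convention, so the magnitude |k₁| is
used and a note is attached whenever k₁ < 0.  A non-positive D⁰_wL
(possible when D_LL exceeds D_ww/|k₁|) is flagged as non-physical but
still returned.  Defaults: D_ww = 10⁻⁶ cm²/s (bulk water, the lower end
of the accepted 10⁻¹⁰–10⁻⁹ m²/s range and the value consistent with the
reference coefficient table); D_LL = 10⁻⁸ cm²/s in the fluid LE phase,
10⁻¹⁰ cm²/s in the gel-like LC phase, and their semi-sum in coexistence.
Because D_LL ≪ D_ww/|k₁| for all fitted regions, the D_LL correction to
D⁰_wL is below 0.01% — the derived table is insensitive to this choice.

The two mappings (forward k-from-D and inverse D-from-k) are not exact
inverses of one another: feeding the derived (D⁰_wL, D⁰_Lw) back through
the forward map with D_LL = 0 returns (|k₁|/k₂′, 1/k₂′), from which
(|k₁|, k₂′) follow by ratio.  Both are exposed separately rather than
forced into a false round trip.

## Synthetic data

The generator samples the TIP forward model per region and adds i.i.d.
Gaussian noise (σ in mN/m) with a caller-supplied seed
(`numpy.random.default_rng`); identical specs are bit-identical.  The
packaged 25 °C DPPC-like reference uses the three-region coefficient set
(LC: p=3, k₁=−0.28, k₂′=1.62; coexistence: p=1, k₁=−0.43, k₂′=0.56;
LE: p=6, k₁=−0.04, k₂′=0.94) on the region ranges LC 40–52,
coexistence 52–75, LE 75–100 Å² with 40 points/region by default.  The
ranges are the package's own synthetic choices resembling a typical DPPC
compression run — no measured boundaries are claimed.  The 45 °C-style
reference is a single smooth supercritical LE-like band (60–110 Å²,
p=3, k₁=0.6, k₂′=0.6 by default, overridable) because no reference
coefficients exist for that regime.

What the generator does *not* emulate: continuity across region
boundaries (regions are generated and fitted independently; the boundary
pressure jumps are reported in metadata), genuinely flat coexistence
plateau physics beyond the p = 1 form, collapse, instrument drift, or
heteroscedastic noise.  Passing recovery tests therefore demonstrate that
the estimator is correct and well-calibrated *under the model's own
assumptions*; they do not certify behavior on real trough data with
correlated or state-dependent errors.

## Numerical choices and edge cases

* Isotherms must be strictly increasing in a_L; loaders sort ascending
  and reject duplicate areas within 10⁻⁹ Å².
* Fit sizes: ≥ 3 points per region (two linear coefficients plus model
  adequacy); rank-deficient designs (other than the structural p = 1
  case) raise.
* Simulation sizes used by the tests and the acceptance script — 40–60
  points/region for round trips and comparisons, 200 replicates at
  σ = 0.1 mN/m and 50 points/region for coverage — are the package's
  standard study conditions; they give sub-second fits and coverage
  estimates with ~0.2% Monte-Carlo error.
* Coverage is evaluated with the exponent fixed at the generating value:
  ±3-stderr coverage is a statement about the linear coefficients
  conditional on the model, and integer model selection under noise is a
  separate discrete problem (see the p = 1 remark above).
* JSON reports are sorted-key with non-finite values serialized as null;
  repeated runs with fixed inputs are byte-identical.

## Known limitations

* The TIP coefficients are convention-bound: fits are comparable only
  within the per-molecule κ(T) convention documented above.
* Auto-segmentation fails by design when no interior slope plateau
  exists (e.g. supercritical isotherms) — pass explicit breakpoints.
* No multi-temperature global fitting, compressibility-modulus analysis
  or collapse detection.
* Cross diffusion coefficients inherit the |k₁| sign convention; a
  negative fitted k₁ signals that the underlying mobility interpretation
  of that region is an effective, not mechanistic, description.
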
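# Methods

## Model

A hollow-fiber membrane reactor hydrolyses racemic ibuprofen ester with
lipase immobilised in the porous fiber wall. The (S)-ester (concentration
S₁, scaled by its bulk feed value) is consumed by inhibited
Michaelis–Menten kinetics; the (R)-ester (S₂) is coupled to it through
base-mediated racemization, which drives the mixture toward the 1:1 state.
Only radial transport is modelled (axial gradients neglected), Fickian
diffusion with constant effective diffusivity, constant fluid properties,
steady state. On the dimensionless annulus x ∈ [1, 2] (inner wall to outer
wall, the published geometry has outer/inner radius ratio 2):

    S₁'' + (1 + B₀)/x · S₁' = Φ² S₁ / ((1 + S₁/Θ)(1 + φξ₂ + ξ₁S₂))
    S₂'' + (1 + B₀)/x · S₂' = γ (S₁ − S₂)/(S₁ + S₂)

No-flux at x = 1; S₁ = S₂ = 1 at x = 2. The Dirichlet outer condition is
the large-B₀ reduction of the convective flux condition
dS/dx = (B₀/x)(1 − S); its exact wall profile 1 − x^(−B₀) is exposed as a
diagnostic (`robin_wall_profile`): at the smallest tabulated Bodenstein
number, B₀ = 8.68, the profile reaches 0.99757 at x = 2, so the
approximation is good to 0.25% there and improves exponentially with B₀.

### Dimensionless groups

| group | meaning | formation |
|---|---|---|
| Φ² | Thiele modulus squared (reaction/diffusion) | a²·α_p·v_max/(D_eff·K_mA) |
| B₀ | Bodenstein number (convection/diffusion) | F/(2π·L·N·D_eff); the radius cancels in r·u(r)/D_eff |
| Θ | Michaelis–Menten group | K_mA/s_A0 |
| γ | racemization group | a²·r_rac/(D_eff·s_T0), r_rac = K_rac·s_OH |
| ξ₁ | (R)-ester uncompetitive inhibition | s_B0/K_uS1 |
| ξ₂ | alcohol non-competitive inhibition | s_A0/K_nI1 |
| φ | by-product molar fraction | s_I/s_A0 |

Bench units mix hours (rates) and minutes (diffusivity); all rates are
converted to a per-minute basis before the groups are formed, so the
groups are dimensionless by construction. When the racemic feed total s_T0
is not given it defaults to 2·s_B0. B₀ is proportional to the volumetric
flow rate (8.68 ↔ 50 mL/min, 34.72 ↔ 200 mL/min for the reference
geometry); prose sources occasionally state the inverse relation, which
contradicts the defining formula and is not followed. The canonical
parameter throughout the package is Φ² (`phi2`), never Φ; any interface
that accepts a plain modulus header squares it explicitly (see
"Modulus convention" below).

## Series solutions

The coupled system is solved by a perturbation homotopy truncated at third
order in the embedding parameter; the printed closed forms carry a
Φ²Θ-linear and a Φ⁴Θ³ term for S₁ and a single γΦ²Θ term for S₂. The
expressions are transcribed term for term with no algebraic
simplification, powers x^(−B₀), 2^(−B₀), 4^(−B₀) evaluated through
exp/log. Both series satisfy the boundary conditions identically (tested
to 1e−10 over random parameter sets). Denominators carry (B₀ − 2);
evaluation within 1e−6 of B₀ = 2 is refused rather than taken through the
analytic limit, since no tabulated operating point approaches it. The
internal identity M = N/8 between the S₂ radial kernel and the S₁
second-order kernel was established symbolically and is exploited only as
a cross-check, never in evaluation.

The S₁ series residual in its governing equation decays with log-log
slope 2 in Φ² (the dominant defect is the γΦ⁴ coupling through the
inhibition denominator, which the printed Φ⁴ term does not carry); the S₂
series is first-order accurate by construction, residual linear in Φ².

### Transcription-level inconsistencies (kept as printed)

These are properties of the published formulas themselves, reproduced
faithfully and documented rather than repaired:

1. **(R)-ester table columns.** The printed S₂ series is exactly the
   solution of the linearised racemization problem driven by the
   first-order S₁ deficit — re-derived symbolically and confirmed — yet
   the published semi-analytical S₂ table columns contain additional
   higher-order feedback (e.g. 1.000675 from the formula vs. 1.000698
   printed at the weak-diffusion point; 1.015860 vs. 1.018490 at
   Φ² = 10). The generating closed form was never printed. These columns
   sit in the package's non-reproducibility register: reproduction runs
   report their deviations but flag them `registered` instead of failing.
2. **Conversion-degree reduction.** The conversion-degree S₁ form should
   reduce to the standard series at X = 0, S₁b = S₂b = 1. Its first-order
   term does, exactly; the printed second-order term is larger by the
   factor (1 + Θ)/Θ (it carries Θ²/((X−1)S₁b − Θ)² where Θ³/(…)³ would
   make the reduction exact). The corresponding acceptance test asserts
   the full identity at 1e−12 and is intentionally left failing as the
   honest record; the true (first-order) identity is tested separately.
3. **Conversion-degree S₂ outer boundary.** The printed conversion-degree
   S₂ expression preserves S₂(2) = 1 only where its driving factor
   1 + S₁b(X − 1) vanishes (e.g. X = 0, S₁b = 1); for general bulk states
   it does not. Kept as printed.

## Numerical oracle

The second-order pair is reduced to four first-order equations and solved
with `scipy.integrate.solve_bvp` (4th-order collocation, adaptive mesh,
residual tolerance 1e−8 default, 1e−10 in table-reproduction mode, 41-point
initial mesh, constant racemic initial guess (1, 1, 0, 0) — the exact
Φ = 0 solution, inside the basin of attraction for every tabulated
parameter set). The solver is deterministic. Each solution records the
max-norm residual of the governing equations over a 201-point grid
(verified ≤ 10× the requested tolerance) and `refine_until_converged`
additionally solves at tolerance/10 and certifies agreement of the two
solutions to 10× tolerance. This oracle reproduces every published
numerical column at x = 1 to all six printed decimals; whether the
original digits came from collocation or a shooting scheme is therefore
immaterial. Table values are rounded to 6 decimals only in
table-reproduction mode; full precision is kept internally.

## Effectiveness factors

Local effectiveness is either the rate ratio v(S₁(x), S₂(x))/v(S₁b, S₂b)
or the concentration ratio S₁(x)/S₁(2); the mean integrated factor over
the annulus is η_m = (2/3)∫₁² x η(x) dx, by adaptive quadrature (absolute
error ≤ 1e−10, cross-checked against a 10⁵-point trapezoid rule).

Two closed forms are shipped, both algebraically η₀(1 − KΦ²) with

    η₀ = (Θ + S₁b)(1 + S₂bξ₁ + φξ₂) / (S₁b (1 + ξ₁ + φξ₂)(Θ + 1))

the zero-Thiele (kinetic-control) limit, equal to the rate ratio
v(1,1)/v(S₁b,S₂b) and exactly 1 at the racemic reference state. The
**literal** printed form and the **table-consistent** variant differ in a
single bracket coefficient (9Φ²/4 vs. 9Φ²/2 in the B₀-linear bracket). An
exhaustive cell-by-cell check shows the table-consistent variant
reproduces all 32 published effectiveness cells to ≤ 5e−5 (observed
≤ 4.9e−7), while the literal form misses them systematically (0.347 vs.
0.433 at the strongest-modulus cell); which one the authors intended
cannot be decided from the source, so both are first-class and the
discrepancy is registered. The three deficit coefficients in play at the
reference base parameters — literal ≈ 6.53e−3, concentration-quadrature
≈ 6.80e−3, table-consistent ≈ 5.666e−3 per unit Φ² — are mutually
inconsistent; the package documents all three rather than adjudicating.

**Modulus convention.** The effectiveness tables tabulate a modulus header
m whose deficit scales as m², i.e. the header enters the closed form as
Φ² = m² (the header is Φ). The profile tables use their stated Φ²
literally (verified against the series). The convention is an explicit
argument at every interface; nothing is guessed.

γ does not appear in either closed form; the published effectiveness
tables omit γ from their captions, consistent with the (R)-ester deviation
having been neglected in η_m. Noted, not asserted as intent.

## Comparison, validity, sensitivity

**Error protocol.** Percent errors are |series − numeric|/numeric × 100
computed after both values are rounded to 6 decimals, matching the
published protocol; column averages are plain means. The strong-diffusion
average reproduces the published 0.018978% to 2.4e−5 points.

**Validity maps.** The admissibility criterion behind the published
validity regions is unstated, so the default criterion here is an explicit,
replaceable choice: the conversion-degree profile on a 101-point radial
grid must be real, finite, within [−1e−6, 1 + 1e−6] for the consumed
species, and the second-order series contribution must nowhere exceed the
first-order one (series dominance, isolated by a Richardson split in the
modulus). The resulting maps are monotone along the modulus axis; the
per-column frontier is the largest valid modulus and a least-squares line
through the frontier gives (slope, intercept, rms). The published frontier
coefficients (2.2819·S₁b + 7.4619 at X = 0, 0.01915·S₁b + 6.261 at
X = 0.99, and the γ-frontier analogues) are stored verbatim as annotations
and are *not* regenerated by the default criterion (which places the
frontier at much larger moduli); the qualitative structure — frontier
linear in the bulk concentration, slope collapsing toward zero as
conversion → 1 — is reproduced and tested. Frontier recovery itself is
validated against a planted synthetic boundary, recovered within one grid
spacing.

**Sensitivity.** Normalised logarithmic sensitivities
|Δη_m/Δq · q/η_m| of the closed-form η_m, central differences with ±1%
relative step (validated against the analytic derivative in Φ to 1e−6
relative), taken with respect to Φ (not Φ²), at the effectiveness-table
base parameters with Φ² = 1 and racemic bulk — the published baseline is
unstated, so this choice is recorded in every report. Results are scaled
to max = 100%. Φ dominates, and φ and ξ₂ have identical sensitivities at
S₂b = 1 because they enter only as the product φξ₂ — which is why the
published split (4.18% for φ, 0% for ξ₂) cannot be regenerated; the
published percentages are annotations. The full ranking under this
computation (Φ > ξ₁ > B₀ > Θ > φ = ξ₂ > γ = 0) also differs from the
published Θ > φ > B₀ > ξ = 0 ordering: ξ₁ and B₀ enter η_m through the
deficit coefficient K even where they cancel in η₀, so their published
null/minor impact is not recoverable from the closed form either. Only
the dominance of Φ and the φ/ξ₂ symmetry are asserted by tests.

## Reproduction pipeline and tolerances

`reproduce_tables` regenerates all eight reference tables from vendored
printed values: effectiveness cells at ≤ 5e−5 absolute, profile
concentration columns at ≤ 2e−6 absolute, percent-error columns at ≤ 1e−3
points. Columns in the non-reproducibility register (the three (R)-ester
series columns and their error columns) are reported with their actual
deviations and flagged `registered`; everything else must pass for the
run to succeed. Regenerating the effectiveness tables under the literal
closed form is the built-in negative control and fails as documented.

## Problem sizes and defaults

Collocation uses a 41-point initial mesh, 10000-node cap; comparison grids
are the published 6-point grid x = 1.0(0.2)2.0; quadratures use adaptive
Gauss–Kronrod with 1e−12 requested accuracy; validity scans default to a
101-point radial grid per cell. All reference computations complete in
seconds on one core.

## Limitations

* Steady state only: no transient kinetics, no enzyme deactivation or
  half-life, no axial gradients, no two-phase partitioning thermodynamics.
* The series solutions inherit every transcription-level defect of their
  printed sources (see the register above); the collocation oracle is the
  authority whenever the two disagree.
* No higher-order series extension beyond the printed truncation.
* The validity criterion and the sensitivity baseline are package choices
  where the source is silent; both are explicit and replaceable.
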
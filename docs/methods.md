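# Methods

## Problem and model

After administration of a ¹⁷⁷Lu-labelled radiopharmaceutical (here the
SST2 antagonist ¹⁷⁷Lu-OPS201 studied in mouse, pig and human cohorts),
the activity retained in an organ or in blood is measured at a handful of
time points and summarized as a time-integrated activity coefficient
(TIAC, also called residence time): the integral over time of the
fraction of administered activity in the region. The TIAC is the
biokinetic input to absorbed-dose calculation; absorbed dose itself
(S-values, phantoms) is out of scope here.

Uptake curves are modelled as sums of decaying exponentials,

    f(t) = Σᵢ Aᵢ · exp(−λᵢ t),      1 ≤ i ≤ 2,

with amplitudes in %IA (organs) or %IA/mL (blood) and *effective* rate
constants λᵢ = λ_bio,i + λ_phys. Because the physical decay of ¹⁷⁷Lu
(half-life 6.647 d, λ_phys = ln 2 / 159.5 h = 4.345·10⁻³ h⁻¹) is part of
every effective rate, all fitted rates are constrained to λᵢ ≥ λ_phys.
Three candidate forms are supported: monoexponential washout,
biexponential washout (both amplitudes ≥ 0), and a two-rate uptake form
A(e^{−λ₁t} − e^{−λ₂t}) with λ₂ > λ₁, which passes through the origin.
Three-or-more-term models are deliberately not offered; the sparse
schedules here cannot support them.

## Fitting

Weighted least squares minimizes Σ((yₖ − f(tₖ))/σₖ)² with per-point σₖ
taken from the curve. When the data carry no uncertainties, σ = 0.10·y is
assumed (a 10% systematic quantification error); an absolute floor of
10⁻⁹ in curve units prevents infinite weights at zero values.

Starting values come from classical curve peeling: a log-linear
regression on the tail gives the slow term, a log-linear fit to the
positive early residual gives the fast term. Because biexponential WLS is
multi-modal, each fit runs from 20 starts (the peeled start plus 19
seeded log-uniform perturbations, factors 10^U(−0.5,0.5)); the best
converged solution is kept, so a fixed seed gives a fully deterministic
fit. `scipy.optimize.least_squares` (trust-region reflective) enforces
the bounds A ≥ 0, λ ≥ λ_phys; the uptake form is optimized in
(A, λ₁, δ=λ₂−λ₁) coordinates so the ordering constraint is a simple
bound, and the covariance is mapped back to (A, λ₁, λ₂). Tolerances are
1e-12 with a 5000-evaluation cap — tight enough that noiseless synthetic
curves are recovered to better than 10⁻⁶ relative error.

The parameter covariance is the inverse Gauss–Newton normal matrix
(JᵀJ)⁻¹ of the σ-weighted Jacobian at the solution — the known-sigma
convention, with no reduced-χ² rescaling, since the 10% error model is
taken as given rather than estimated from the residuals.

Model selection uses the corrected Akaike criterion
AICc = n ln(SSR_w/n) + 2k + 2k(k+1)/(n−k−1) on the weighted SSR, with
near-ties (|ΔAICc| < 0.01) resolved toward fewer parameters. The SSR is
floored at n·10⁻²⁴ so that on noiseless data, where every candidate
reaches machine-zero residuals, the parameter-count penalty decides. The
AICc requires n ≥ k+2; candidates with fewer than k+1 points are skipped
outright. Note that with n = 8 points the small-sample penalty is severe:
a biexponential whose fast phase is weakly expressed relative to 10%
noise is *correctly* classified as monoexponential much of the time. The
packaged model-selection validation therefore uses a truth with both
phases strongly expressed (amplitudes 50/10, rate ratio 35), where the
generating form is recovered in ≳99% of noisy replicates.

## TIAC and error propagation

The fitted model is integrated analytically over [0, ∞):
TIAC = Σᵢ (Aᵢ/100)/λᵢ — hours for organs, h/mL for blood concentration.
(The per-mL blood coefficient is reported in h/mL; multiplying by a blood
volume to obtain a whole-blood TIAC is done only when the species profile
actually provides a volume.) Integration starts at t = 0, i.e. the fitted
function is back-extrapolated below the first sample. Every organ TIAC is
checked against the physical-decay bound Σ (Aᵢ/100)/λ_phys (nothing
leaves except by decay); the pipeline logs a degeneracy warning when a
TIAC comes within 1% of the bound.

The standard error is first-order (delta-method) propagation,
se = √(gᵀ C g), with g the closed-form gradient of the TIAC in the free
parameters. An independent Monte-Carlo oracle draws parameters from
N(θ̂, C), rejects draws violating λ ≥ λ_phys (or λ₂ ≤ λ₁ for the uptake
form), and reports the sample SD; a rejection rate above 50% aborts,
since that signals the Gaussian/linear approximation has broken down.
In the linear regime (parameter CVs of a few percent) the two agree to
well under 2%; near the rate floor the delta method genuinely
overstates the truncated spread and no agreement should be expected.

## Interspecies extrapolation

Five methods map an animal TIAC to a predicted human TIAC using
whole-body mass m_WB and, where needed, organ masses m or the fitted
kinetics:

1. **Same biodistribution** — identity.
2. **Relative mass scaling** — multiply by (m/m_WB)_human / (m/m_WB)_animal.
   Refused when either organ mass is missing (mouse blood, whose total
   volume is unknown, is the canonical refusal).
3. **Time scaling** — stretch biological time by c = (m_WB,h/m_WB,a)^¼.
   Implemented on the fitted model, not the bare TIAC: each rate becomes
   λ → λ_phys + (λ − λ_phys)/c, and the TIAC is re-integrated. Physical
   decay is a property of the nuclide, not of the species, so it is not
   stretched by default; `scale_physical_decay=True` gives the naive
   variant λ → λ/c. For washout models the default satisfies
   TIAC ≤ TIAC_scaled ≤ c·TIAC term by term. For uptake models no such
   bound holds — slowing biological time also slows the uptake, and when
   the washout rate is near λ_phys the scaled integral can be *smaller* —
   so the bound is asserted only over the washout family.
4. **Combined** — method 3 followed by method 2 (exactly that
   composition, tested as such).
5. **Allometric scaling** — multiply by (m_WB,h/m_WB,a)^(b−1) with an
   organ-specific exponent; defaults b(liver) = 0.92, b(kidneys) = 0.85.
   The kidney exponent follows the equation-level value rather than the
   alternative 0.82 quoted in prose in the source literature, because
   0.85 reproduces the published mouse kidney scaling to within rounding
   (0.45 vs 0.44) while 0.82 does not (0.36). Both are configurable.
   Regions without a configured exponent (blood) are skipped.

Methods 3–4 refuse to run from a bare TIAC: without the fitted rates the
time-scaled integral is not defined, and approximating it would silently
change the method.

The comparison report divides the larger of (human, scaled) by the
smaller, flags the direction (under/over-estimation), and rounds for
display: factors ≥ 3.5 to the nearest integer, smaller factors to one
decimal — the convention in which "4× underestimated" style statements
are quoted.

## Synthetic data

The generator mirrors the functional form the analysis assumes — no
compartmental mechanism, just ground-truth exponential models sampled on
the cohort schedules (mice: organ harvests to 168 h, blood 1–72 h; pigs:
scans at 0.5, 2, 3, 4, 50, 100, 150, 250 h, blood to 300 h; humans:
scans at 1, 3, 24, 72 h, blood 0.3–23 h). Noise is independent
multiplicative Gaussian, value = truth·(1 + ε), ε ~ N(0, cv), cv = 0.10
by default to match the assumed 10% quantification error; negative draws
are clipped to zero (unphysical), and σ = max(cv·truth, floor) is
attached to each sample. Whether the study's "systematic" 10% acted as
correlated or independent error is unknowable from the outside; the
generator uses independent per-point noise and exposes cv for
sensitivity studies.

Default truths are chosen so blood fast-phase effective half-lives equal
the cohort values (mouse 1.8 h, pig 1.7 h, human ~0.5 h), the pig blood
late phase is 58 h, every rate contains λ_phys, and organ TIACs land in
the observed 0.7–8 h range (pig kidneys 7.6 h vs the measured 7.67 h,
and so on). What passing tests on these data show is that the
*estimation chain* is correct under its own assumptions; they cannot
validate the exponential model against real physiology, VOI
quantification error, or inter-animal variability, none of which the
generator emulates.

Statistical performance on the default pig-kidney scenario (biexponential
truth, 8-point schedule, cv = 0.10, 200 seeded replicates, generating
form fitted): median relative bias about −2% (fast rate), −1% (slow
rate), +0.7% (TIAC), and the truth lies within ±3 SE of the estimate in
97% of replicates.

## Numerical and design choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); reruns are byte-identical, including CSV
  output (floats serialized with `repr`, re-read with round-trip parsing).
- Units are explicit strings (`pct_ia`, `pct_ia_per_ml` → TIAC units `h`,
  `h_per_ml`); mixing units within a group is an input error. Published
  tables disagree on the blood unit's orientation (ml/h vs h/ml); this
  package standardizes on h/mL, the integral of a per-mL fraction.
- Whole-body masses default to the cohort means (mouse 26 g, pig 28 kg,
  human 61 kg). Organ masses for relative mass scaling were never
  published; the shipped profile file carries clearly-marked literature
  assumptions (ICRP-style human values, standard rodent/pig values) and
  every mass is overridable.
- Analysis problem sizes (200 replicates for recovery/selection studies,
  10⁵ Monte-Carlo draws for the SE oracle, 100 random models for the
  integral cross-check) were chosen to make the Monte-Carlo error of each
  check at least an order of magnitude smaller than the tolerance it
  tests.

## Known limitations

- Two exponential terms maximum; late-phase kinetics needing a third
  phase would be mis-modelled.
- The human 4-point scan schedule cannot support the 4-parameter
  biexponential at all (n ≥ k+1 fails), so human organ fits choose
  between the mono and uptake forms — an honest reflection of short
  clinical follow-up.
- The delta-method SE is unreliable when a fitted rate sits near the
  λ_phys floor; the MC oracle's rejection guard detects, but does not
  repair, that regime.
- Exact reproduction of the published per-dataset fit parameters is not
  possible: the underlying fitted λ values and organ masses live in
  unavailable supplementary material, so only closed-form scaling of the
  published TIACs (methods 1 and 5, and the comparison factors) is
  checked against printed values.
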
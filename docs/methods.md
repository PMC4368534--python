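# Methods note

This note records the modelling conventions, default parameters and numerical
choices implemented in `cowbw`, including the places where the package had to
resolve an ambiguity.

## 1. Weight conversions

Two relations are provided for each conversion, selectable by flag
(`power` default, `linear` alternative):

| Conversion | Power form | Proportional form |
|---|---|---|
| fed → shrunk | `SBW = 0.8084 · BW^1.0303` | `SBW = 0.9763 · BW` |
| shrunk → empty (non-pregnant) | `EBW_np = 0.8424 · SBW_np^1.0122` | `EBW_np = 0.9092 · SBW_np` |

The power forms imply weight-dependent ratios (SBW/BW 0.961 at 300 kg rising
to 0.986 at 700 kg; EBW/SBW 0.9031 to 0.9125). Inputs outside the observed
development range (roughly 300–700 kg fed weight) are computed but flagged
with an `ExtrapolationWarning`. A pregnant cow's empty weight adds the
pregnancy compound back whole: `EBW_p = EBW_np(SBW_np) + PREG` (the compound
has no gut fill).

## 2. Pregnancy-compound decomposition

For a pregnant cow with shrunk weight `SBW_p`, condition score `BCS`, days of
pregnancy `DOP` (0 encodes non-pregnant) and expected calf birth weight `CBW`
(default 28 kg for *Bos indicus*):

1. **Gravid uterus**: `GU = 0.008010 · CBW · BCS^0.3225 ·
   e^((0.02544 − 0.0000286·DOP)·DOP)`. When BCS is missing the BCS-free curve
   `GU = 0.007521 · CBW · e^((0.03119 − 0.00004117·DOP)·DOP)` is used and a
   `FallbackWarning` raised. Both are condition-score-scaled forms of curves
   originally fitted with scales 0.2243 and 0.2106 for a 28-kg calf.
2. **Non-pregnant uterus**: `UT_np = 0.0012 · SBW_np`. Because `SBW_np` is
   the unknown being solved for, a provisional maternal weight
   `SBW_p − GU + 0.6` (additionally `− 2` when `DOP > 240`, a placeholder for
   udder accretion) stands in; the 0.6 kg is the uterus of a reference
   500-kg cow. This makes `UT_np` (hence the chain) piecewise in DOP with a
   negligible jump (≈2 g) at day 240.
3. **Gravid-uterus accretion**: `GU_dp = max(GU − UT_np, 0)`; in very early
   gestation the fitted GU curve can fall below `UT_np`, in which case the
   accretion is clamped to zero with a `ClampingWarning`.
4. **Udder**: `UD_np = 0.00589 · SBW_prov · BCS^0.2043` (BCS default 5.6,
   the study mean, when missing), growing past a fitted breakpoint at day
   238 as `UD_p = UD_np · e^(0.0109 · (DOP − 238))`. The accretion
   `UD_dp = UD_p − UD_np` is **counted in the compound only after day 240**
   — the decomposition convention gates at 240 even though the fitted
   breakpoint is 238; both constants are exposed in `EquationParams`.
5. **Compound and maternal weight**: `PREG = GU_dp + UD_dp`,
   `SBW_np = SBW_p − PREG`, exact identities by construction.

The udder term uses the provisional maternal weight (`SBW_p − GU + 0.6 − 2`)
rather than the final `SBW_np`; the two differ by about a gram and the
provisional form reproduces the published worked chain. `PREG ≥ SBW_p` raises
an `InconsistencyError`.

**Breed adaptation.** For *Bos taurus* the gravid uterus uses the classical
exponential curve `GU (g) = 19.32 · CBW · e^((0.02 − 0.0000143·DOP)·DOP)`
(CBW default 38.5 kg) and the fixed factors `SBW = 0.96·BW`,
`EBW = 0.851·SBW`. `crossbred` averages the two full, independently computed
chains field by field.

## 3. Fitting

All families are fit by nonlinear least squares on the **original scale**
(log-transforms are used only to produce starting values, since they would
otherwise reweight the errors). The solver is Gauss–Newton with a central
finite-difference Jacobian and step halving; convergence is a relative SSE
change below 1e-8 (1e-12 for power laws) or a stationary point. Standard
errors come from `s²·(JᵀJ)⁻¹`. The no-intercept linear family has the closed
form `β = Σxy / Σx²`.

The segmented udder model is fit by profiling the breakpoint over the integer
grid 100–280 days: for each candidate the remaining parameters are estimated
by Gauss–Newton from log-linearized starts and the SSE-minimising candidate
wins. A training set with no records on both sides of any candidate raises a
`BreakpointError`.

## 4. Evaluation statistics

- **Joint test**: regress observed on predicted and test
  `(β₀, β₁) = (0, 1)` with the exact F statistic
  `((SSE_restricted − SSE_full)/2) / (SSE_full/(n−2))` on `(2, n−2)` df.
- **Cb** (Lin's accuracy factor): `2 / (v + 1/v + u²)` with
  `v = s_pred/s_obs`, `u = (mean_pred − mean_obs)/√(s_pred·s_obs)`
  (population moments). Cb ∈ (0, 1], 1 iff means and SDs match.
- **MSEP partition**: mean bias `(ȳ_p − ȳ_o)²` + systematic
  `(s_p − r·s_o)²` + random `(1 − r²)·s_o²`; the three terms sum to the MSEP
  exactly (population moments throughout).
- **AICc**: `n·ln(SSE/n) + 2K + 2K(K+1)/(n−K−1)` with `K = k_params + 1`
  (the error variance counts); comparisons report the evidence ratio
  `e^(Δ/2)` and the probability `ER/(1+ER)`.

## 5. Cross-validation

20 replicates, each a random 70% subsample (`round(0.7·n)` records); fits on
the subsample, deviations `d = predicted − observed` on the held-out 30% by
default (an `all`-records mode is available — the protocol description is
ambiguous on this point). **RMSE is the standard deviation of the pooled
deviations** (the "standard error of d" convention), so a pure constant bias
yields RMSE 0 but a nonzero MAE; a root-mean-square variant that includes the
bias is available via `rmse_mode="rms"`. R is the per-replicate
predicted-observed correlation reported as mean ± SD, and R² = (mean R)².
Replicates whose fit fails or does not converge are excluded with a warning.

## 6. Synthetic herd generator

The generator emulates the study design behind the coefficients: 49 cows, 32
pregnant (gestation groups 136/189/239/269 days, the rest at day 0), two
feeding levels with maternal shrunk weights ~543 (HIGH) and ~460 kg (LOW),
SD 45 kg truncated to [366, 701] kg, condition scores on the 0.5 grid in
[3, 8], 28-kg expected calves. Latent truths come from the package's own
decomposition; observed values add multiplicative Gaussian noise with CVs
defaulting to the published cross-validation error percentages (SBW 1.0%,
EBW 2.1%, GU 19%, UT 14%, UD 12%); an additive mode exists. Fed weight is
obtained by inverting the shrunk-weight power relation.

Because `UT_np` depends on the provisional maternal weight, the compound
depends weakly on `SBW_p` itself; the generator draws `SBW_np` and solves the
fixed point `SBW_p = SBW_np + PREG(SBW_p)` so a zero-noise herd round-trips
through `adjust` to machine precision. `generate_fit_dataset` draws
covariates over each family's validity envelope (gravid-uterus gestation days
over 135–270, matching the span the curves were estimated on) and applies a
single multiplicative noise CV. Default seed 20150320; all derived seeds stay
below 2³¹. The generator does **not** simulate intake, growth trajectories
over time, or slaughter-group attrition, and within-level weight dispersion
is an approximation (configurable).

## 7. Limitations

- Coefficients were developed on mature Nellore cows of 300–700 kg; use
  outside that envelope extrapolates (warned, not blocked).
- The *Bos taurus* path relies on fixed conversion factors and an external
  gravid-uterus curve; condition-score effects are unavailable there.
- DOP, BCS and CBW are treated as known inputs; their measurement error is
  not propagated.
- The decomposition is deterministic — no uncertainty intervals on PREG.
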
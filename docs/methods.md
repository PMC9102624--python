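# Methods

## The switch model

Each GAPDH subunit is treated as an independent kinetic unit ("uniform and
independent oxidation"): the package tracks concentrations of subunit-state
pools, not combinatorial tetramer configurations, so a tetramer-level state
explosion and inter-subunit correlations are deliberately out of scope.
The default (experimentally supported) mechanistic order, variant (i), is

| step | reaction | constant | default |
|---|---|---|---|
| 1 | C<sub>c</sub>(SH) + H₂O₂ → C<sub>c</sub>(SOH) | k′ (M⁻¹s⁻¹) | 9.4 |
| 2 | C<sub>v</sub>(SH) + H₂O₂ → C<sub>v</sub>(SOH) | k″ (M⁻¹s⁻¹) | 9.4 |
| 3 | 2 SOH → thiosulfinate (committed) | k‴ (s⁻¹) | 100× fastest oxidation pseudo-rate |
| 4 | thiosulfinate → thiosulfonate | k_hyd (s⁻¹) | ln 2 / 900 (t½ ≈ 15 min) |
| 5 | thiosulfonate + downstream SH → C<sub>c</sub>(SO₂H) + disulfide | k_res (s⁻¹) | 100 × k_hyd |
| 6 | resolved → unfolded, NAD⁺ released | k_unfold (s⁻¹) | 19.95 × 10⁻⁶ |
| side | C<sub>c</sub>(SOH) + H₂O₂ → C<sub>c</sub>(SO₂H) | k_side (M⁻¹s⁻¹) | 0.4 |

Variant (ii) swaps the oxidation order; variants (iiia/iiib) build the
parallel-consecutive topology in which either residue may be oxidized
first.  Enzymes whose vicinal cysteine is replaced by serine (the
*L. acidophilus*-type inventory) have no condensation path at all: the only
route past the sulfenic acid is the slow side branch, which is why such
enzymes resist irreversible peroxide inactivation.

Choices worth making explicit:

* **k‴ default.** Only the ordering "condensation faster than oxidation"
  is constrained by the data; the factor 100 makes the sulfenic pair a
  committed intermediate without stiffening the system needlessly.  The
  simulator warns if a supplied rate set violates the ordering.
* **Resolution partner.** The thiol attacking the thiosulfonate is drawn
  from the same subunit's downstream pool (intrachain), consistent with the
  gel-shift evidence of one disulfide plus one reduced cysteine within a
  subunit; for inventories with no downstream thiol (yeast-like) the pool
  network is unchanged and the partner is read as the sibling subunit's
  thiol.  Inter-subunit disulfide multimers seen after overnight alkaline
  incubation are an out-of-network end state, not a kinetic species.
* **Unfolding and NAD⁺ release** are one first-order step: the data tie
  them temporally without resolving separate rates.
* **Temperature is a label.**  Rate constants are taken as supplied; no
  Arrhenius correction is attempted across the 14 °C / 37 °C conditions.
* **Rate-law caveat.**  The overall reaction appears kinetically third
  order (rate ∝ [E][H₂O₂]²) when k‴ exceeds the oxidation pseudo-rates;
  the package realizes this as elementary mass action on enzyme species
  rather than as a literal product-dependent power law, which would be
  inconsistent with a product-independent consecutive mechanism.

### Numerics

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol 1e-12 (rate
constants span five orders of magnitude, so a stiff-capable integrator is
required).  Cumulative H₂O₂ consumption is integrated as an extra state,
making the closure consumed(t) + [H₂O₂](t) = [H₂O₂](0) a genuine solver
invariant rather than an identity; trajectories satisfy subunit and sulfur
conservation to better than 1e-8 relative.  The absolute tolerance matters
when pool concentrations are far below 1e-12 M — the closed-form
equivalence test therefore passes tighter tolerances explicitly.

## Fitting

All fitters use lmfit with rate parameters bounded below at zero,
data-driven initial guesses (initial-slope estimates for second-order
fits, time-to-fraction estimates for exponentials), and report estimates
only from converged fits, with standard errors, residuals and r² on the
fitted scale.

* **Second-order H₂O₂ consumption.**  The fit model is the consecutive
  two-step scheme itself, integrated numerically at full unequal-
  concentration mass action with the known side branch fixed at
  0.4 M⁻¹s⁻¹ — not a log-linearized or parallel-pools approximation.  The
  1:1 amplitude split of the two phases is then automatic (each step
  consumes one equivalent per subunit), and noiseless round-trips are
  exact.  Residuals are scaled by the trace's consumption range purely for
  optimizer conditioning.  A collapse of the two constants within their
  joint confidence interval is flagged "effectively monophasic" and the
  single-constant fit is reported for both.
* **Multiphase DTNB release.**  Phases are parallel exponentials with
  amplitudes fixed by the phase stoichiometry (1:1:2 for the native
  enzyme) times a common per-unit amplitude; phases are resolved by
  stoichiometry, not sequential convolution, which is adequate when the
  constants are separated ≥2× (closer pairs are merged and flagged).
* **TNB–thiosulfinate (2:1).**  With the first step rate-determining the
  second TNB consumption is instantaneous, giving d[TNB]/dt =
  −2k[TNB][TS]; the conserved combination [TNB] − 2[TS] yields a closed
  form used directly in the fit, anchored on the standardized initial TNB
  concentration rather than the noisy first sample.
* **Limited first-order NAD⁺ rise.**  y = y₀ + plateau·(1 − e^(−kt)); the
  fit is declared unidentifiable when the window covers < 0.2 of 1/k.
* **IC₅₀.**  Four-parameter log-logistic with positive Hill slope
  (activity falls with dose).

## Power-law stoichiometry

Only the ratio of exponents in y^α′ = x^β′ is identifiable (it is the
reciprocal log–log slope of y on x), so β′ is fixed — at 1 by default,
matching the one-subunit normalization of the inactivation axis.  Pairs
with x or y < 0.02 are dropped before the log transform (log-space noise
amplification), and y is normalized by the total consumable H₂O₂ (two
equivalents per subunit, eight per tetramer) so that x and y share [0, 1];
the raw-difference alternative only rescales the intercept, not the slope.
For equal oxidation constants the two-step series gives α′/β′ ≈ 1.7 over a
full course sampled to x ≈ 0.95 and tends to 2 exactly as x → 0 (series
expansion: x ≈ 2y²); a one-event mechanism gives exactly 1.  Note that
strongly unequal constants push α′ above 2 — with k′ ≫ k″ the fast first
oxidation spends H₂O₂ well before subunits commit — so an experimental
α′ slightly above 2 is compatible with a finite k″/k′ ratio and need not
indicate extra consumption.

## Synthetic data

Generators emulate the standard working conditions as defaults: 2.5 µM
tetramer, 1.5 mM H₂O₂, 5 mM DTNB; oxidation constants 9.4/9.4 (pH 7),
13.7/6.6 (pH 7.8), 25.6/2.6 (pH 9).  Noise is additive Gaussian on the
observed signal (photometric error), seeded and reproducible; "1 % noise"
is defined as 1 % of the trace's dynamic range, because the H₂O₂ signal
decays by only ~1.3 % of its absolute value at these concentrations and a
percent-of-signal convention would drown the kinetics.  Replicate count
read-outs use the observed replicate scatter (≈0.5–0.6 counts per
tetramer) as their default noise.  For the NAD⁺ assay the noise sd
(2.8 % of the plateau over a two-half-life window of 60 points) is
calibrated so the fitted standard error reproduces the reported
1.75 × 10⁻⁶ s⁻¹; at that noise the single-trace estimate scatters with
~9 % sd, which recovery tests therefore assess as a median over seeds.
Sampling grids are logarithmic for decays and saturating rises, linear for
consumption traces and titrations.  Ground truth goes to a sidecar file,
never into the trace, so recovery studies are blind.

What the generators do **not** emulate: instrument drift, multiplicative
or heteroscedastic noise, mixing dead time, temperature excursions, and
enzyme heterogeneity.  Passing recovery tests therefore demonstrate
estimator correctness and precision under the stated noise model, not
robustness to systematic instrumental error in real data.

## Problem sizes

Simulations use 120–400 time points per trace; recovery studies use 100
seeds for the second-order fitters and 20–100 for the faster estimators —
enough for stable medians while keeping the full suite comfortably quick
on a single CPU.

## Known limitations

* Subunit independence is assumed throughout; cooperative or half-of-sites
  behaviour would require a tetramer-state model.
* The biphasic amplitude constraint (1:1) is built into the mechanism; if
  the two phases had genuinely unequal amplitudes the fit would absorb the
  difference into biased rate constants.
* Michaelis–Menten parameters of the activity assay are not modelled; only
  fractional activities enter the stoichiometry analysis.
* The hydrolysis/resolution tail is parameterized, not independently
  fitted: no assay in the package constrains k_res separately from k_hyd.
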
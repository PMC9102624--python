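# redoxswitch

Quantitative kinetics of the GAPDH two-cysteine redox switch.

Glyceraldehyde-3-phosphate dehydrogenase (GAPDH) is inactivated by hydrogen
peroxide through a dedicated two-cysteine switch: the catalytic cysteine
C<sub>c</sub> (C152 in the human enzyme) and the vicinal cysteine
C<sub>v</sub> (C156) are oxidized in sequence to sulfenic acids, which
condense to an intrachain thiosulfinic ester — an irreversible, committed
product.  Slow hydrolysis of the ester to the thiosulfonate and its
resolution by a downstream thiol leave each subunit with one
C<sub>c</sub>(SO₂H), one mixed disulfide and one remaining free thiol,
followed by subunit unfolding and NAD⁺ release.  `redoxswitch` packages
this mechanism as

* a **mass-action simulator** of the per-subunit reaction network

  E + H₂O₂ →<sup>k′</sup> E(SOH) + H₂O₂ →<sup>k″</sup> E(SOH)₂
  →<sup>k‴</sup> thiosulfinate → thiosulfonate → C<sub>c</sub>(SO₂H) +
  disulfide → unfolded,

  with a slow side branch E(SOH) + H₂O₂ → C<sub>c</sub>(SO₂H)
  (0.4 M⁻¹s⁻¹) and mechanism-order variants (C<sub>c</sub> first,
  C<sub>v</sub> first, parallel-consecutive);
* **nonlinear least-squares fitters** for every assay read-out: integrated
  second-order H₂O₂ consumption (mono/biphasic), pseudo-first-order
  Racker-band (365 nm) quench decays, stoichiometry-constrained multiphase
  DTNB/TNB release (phases 1:1:2), 2:1 TNB–thiosulfinate decays with
  rate-determining first step, limited first-order NAD⁺ dissociation, and a
  four-parameter log-logistic IC₅₀;
* **power-law stoichiometry inference**: fitting paired fractional H₂O₂
  consumption *y* and fractional irreversible inactivation *x* to
  *y*<sup>α′</sup> = *x*<sup>β′</sup>, where α′/β′ reads off the number of
  oxidation events per inactivation event (≈2 for the switch, ≈1 for
  single-alkylation controls);
* **Ellman-assay bookkeeping** (DTNB/TNB, ε₄₁₂ = 14 150 or 14 100
  M⁻¹cm⁻¹; NTSB sulfitolysis, 1 TNB per disulfide) converting absorbances
  to cysteine, disulfide and adduct counts per subunit or tetramer;
* a **synthetic-data module** generating every assay trace with known
  ground truth and seeded Gaussian noise, so all estimators are testable
  by blind recovery.

Intended users: redox-biochemistry and systems-biology groups who need a
reproducible quantitative scaffold for cysteine-switch kinetics — either to
analyse their own traces or to run design/recovery studies before an
experiment.

## Worked example

Generate one synthetic trace per assay at the pH-7 working conditions
(2.5 µM tetramer, 1.5 mM H₂O₂, 1 % trace noise), then fit the
H₂O₂-consumption trace and the inactivation series:

```sh
$ redoxswitch synth --seed 7 --preset ph7 --out traces
$ redoxswitch fit traces/h2o2_consumption.csv --model monophasic
model=second_order_monophasic
n=120
r_squared=0.998514
converged=True
k=9.3553709 +/- 0.07224
b0=0.0014999733 +/- 4.099e-08
$ redoxswitch stoich traces/inactivation_series.csv
alpha_prime=1.66693
beta_prime=1
alpha_over_beta=1.66693
r_squared=0.982468
n=12
```

The fitted `k` is the bimolecular oxidation constant in M⁻¹s⁻¹; the
generator's hidden truth (stored in the sidecar
`traces/h2o2_consumption.truth.txt`, never in the trace) was 9.4, so the
1 % noise run recovers it to ~0.5 %.  `alpha_over_beta ≈ 1.7` is the
power-law stoichiometry of the two-step switch sampled over the full
oxidation course (it approaches 2 exactly in the early-time limit, against
1.0 for a one-event mechanism).

Simulating the network to completion recovers the mechanism's end-point
stoichiometry, two H₂O₂ per subunit:

```sh
$ redoxswitch simulate --preset ph7 --duration 3600 --out traj.csv
endpoint_h2o2_per_tetramer=8
```

The same operations are available as a library:

```python
import redoxswitch as rs

sc = rs.PRESETS["ph9"]
trace, truth = rs.gen_h2o2_trace(
    sc.rates, sc, noise=rs.NoiseSpec(sd=0.01, seed=1, relative_to_range=True))
fit = rs.fit_second_order_biphasic(trace, sc.equiv_conc)
fit["k_prime"], fit["k_dprime"]   # fast and slow oxidation constants
```

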
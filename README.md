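# nestedwell

Quantitative analysis of specific versus nonspecific transcription-factor–DNA
binding from label-free biosensor titration curves.

Transcription factors find their target sites against a vast background of
nonspecific DNA, and the free-energy gap between docking on the consensus
sequence and merely touching generic DNA is surprisingly hard to measure.
`nestedwell` implements a differential analysis for experiments that measure
both at once: paired DNA probe spots — identical except for the presence of
the consensus site — exposed to stepwise increasing protein concentration
while the bound surface density σ(t) is recorded per spot.

## Model

Binding is described by a sequential two-state ("nested-well") scheme: the
protein first binds any DNA nonspecifically, and only from that state can it
dock specifically,

    unbound  ⇌(kon1·c / koff1)  nonspecific  ⇌(kon2 / koff2)  specific

with K1 = koff1/kon1 the nonspecific dissociation constant (nM) and
K2 = koff2/kon2 the dimensionless selectivity coefficient (equilibrium ratio
of nonspecifically to specifically bound protein; small K2 = strong
selectivity).  The whole system equilibrates on a Langmuir isotherm with

    Kd = K1·K2/(1+K2)        ⇔        K2 = Kd/(K1 − Kd),

so measuring Kd on the specific probe and K1 on its nonspecific partner
yields K2 directly.  Step relaxation is a double exponential
σ(c,t) = Σ(c)(1 − B·e^(−t/τL) − (1−B)·e^(−t/τS)); when the inner exchange is
fast, τL → 1/(kon1·(c + Kd)) and the kinetics is nearly exponential, which
justifies the per-step fits σ(t) = Σ(c)(1 − e^(−Γ(c)t)) with
Γ(c) = kon·c + koff.  Across temperatures, ln K2 = ΔH/(RT) − ΔS/R splits the
selectivity into enthalpy and entropy; ΔG = RT·ln K2 (negative when docking
is favoured).

The package contains the closed-form model with an independent ODE oracle
(`nw_model`), a seeded synthetic sensorgram generator (`synthetic`), the
per-step reduction (`trace_fitting`), condition-level estimation including
the shared-Σ∞ Langmuir global fit, the joint kinetic fit and the van't Hoff
regression (`inference`), and CSV/JSON formats plus a CLI (`io`, `cli`).

## Worked example

Simulate a paired titration at the default study conditions (K1 = 200 nM,
K2 = 0.16, kon1 = 1.6e-5 s⁻¹·nM⁻¹, 0.08→50 nM doubling ladder, 30 °C,
150 mM NaCl, noiseless) and run the full pipeline:

```sh
nestedwell simulate --seed 1 --out-dir demo
nestedwell run-all --traces demo/traces.csv --manifest demo/manifest.json \
    --out demo/summary.json
```

which prints

```
wrote demo/summary.json: K2 = 0.160103, Kd_sp = 27.61 nM, Kd_ns = 200.1 nM
```

The summary JSON contains, among others,

```
"Kd_specific_nM":    27.60993565891472,
"Kd_nonspecific_nM": 200.06065008878093,
"Sigma_inf":         1000.2518757188018,
"K2":                0.16010334170081603,
"dG_kcal_per_mol":   -1.103483100084946,
"ddG_kcal_per_mol":  1.1929388937449263
```

Reading these numbers: the specific probe binds ~7× more strongly
(Kd ≈ 27.6 nM vs K1 ≈ 200 nM), yet the selectivity coefficient K2 ≈ 0.16
corresponds to a specific-vs-nonspecific free-energy gap of only
ΔG = RT·ln K2 ≈ −1.1 kcal/mol: of 10 proteins bound to the specific probe,
10/(1+K2) ≈ 8.6 are actually docked on the consensus site.  The recovered
values match the generator's inputs to better than 0.1% (Kd) and 1e-3 (K2),
which is the round-trip accuracy the test suite enforces.

The same API is available in Python:

```python
from nestedwell import generate_probe_pair, analyze_pair, vant_hoff_fit, \
    generate_k2_temperature_series

sp, ns = generate_probe_pair(noise_sd=10.0, seed=1)   # 1% measurement noise
summary = analyze_pair(sp, ns, regressor="corrected")
thermo = vant_hoff_fit(generate_k2_temperature_series(rel_noise=0.05, seed=1))
print(summary["K2"], thermo.dH, thermo.dS)
```

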
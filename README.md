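# rbdyn

Single-cell analysis of cell-cycle-dependent degradation of the
retinoblastoma protein (Rb), for researchers studying how mammalian cells
commit to division at the G1-S transition.

Rb is a cell-cycle inhibitor whose concentration falls through G1 as cells
grow — not because synthesis changes, but because un- and
hypo-phosphorylated Rb is actively degraded (via the E3 ubiquitin ligase
UBR5) until Cdk-dependent hyperphosphorylation stabilises it at the G1-S
transition. `rbdyn` packages the quantitative toolchain behind this result:

* **synthetic cohorts** (`rbdyn.synthetic`) — seeded generators for
  induction-withdrawal (decay) experiments and cycling live-cell movies:
  48-hour traces at 20-minute cadence with growing nuclei, a Geminin-type
  S-G2 reporter, an HDHB-type Cdk-activity ratio, and multiplicative
  measurement noise. Per-cell half-lives are drawn from two-piece
  log-normal distributions calibrated exactly to a median and a central-75%
  range (`rbdyn.distributions`).
* **trace processing** (`rbdyn.traces`) — background correction
  (raw − median background × area), concentration as corrected intensity /
  area^(3/2) (nuclear volume proxy), Geminin-based phase annotation with the
  7-hour early-G1 rule, trace alignment and mean-normalisation.
* **half-life estimation** (`rbdyn.halflife`) — per-cell fits of
  N = N₀·exp(−kt) by least squares on log-intensity (t₁/₂ = ln2/k), phase
  and condition stratified summaries, bootstrap condition comparisons.
* **Cdk dynamics** (`rbdyn.cdk`) — logistic-fit detection of the
  cytoplasm/nucleus ratio inflection, the 5-hour Cdk-low/high rule,
  birth-concentration vs G1-length correlations, and a person-time hazard
  of the G1-S transition binned by concentration.
* **kinetic model** (`rbdyn.model`) — the growth-coupled turnover model

      dM/dt  = γ·M^δ
      dRb/dt = α·M^δ − β(t)·Rb,      c = Rb/M

  with a step in the degradation rate at the G1-S transition
  (β = β₀ in G1, β = ε·β₀ in S-G2-M, ε = 0.2: an 80% step down), a
  concentration-threshold G1-S trigger, an S-G2-M timer, division that
  halves M and Rb, Euler-forward integration and burn-in to the limit
  cycle. A synthesis-step variant (constant β, α stepped up in S-G2-M)
  serves as the alternative hypothesis.

## Worked example

Fit phase-stratified half-lives in the packaged reference conditions
(200 cells per phase, 5% frame noise) and compare wild type with a
UBR5-knockout condition in which early-G1 degradation is halved:

```bash
python analysis/02_fit_halflives.py
```

```
WT: fitted 400 cells (0 failures)
  WT/earlyG1: median 6.37 h, 75% range 5.18-9.41 h
  WT/SG2: median 37.22 h, 75% range 28.41-44.81 h
  UBR5-KO/earlyG1: median 12.78 h, 75% range 10.69-19.25 h
  UBR5-KO/SG2: median 36.82 h, 75% range 29.65-44.85 h
  KO/WT earlyG1: ratio 2.01 (95% CI 1.89-2.17)
  KO/WT SG2: ratio 0.99 (95% CI 0.95-1.03)
```

Rb is degraded fast in early G1 (half-life ~6.4 h) and is ~6-fold more
stable in S-G2; removing the G1 degradation pathway doubles the early-G1
half-life and leaves S-G2 untouched. The other drivers follow the same
pattern: `analysis/01_generate_cohorts.py` exports the cohorts,
`analysis/03_cdk_statistics.py` computes the Cdk classification and the
concentration statistics of G1 exit (positive birth-concentration vs
G1-length correlation, hazard falling with concentration, a flat hazard on
the constant-rate null cohort), and `analysis/04_model_dynamics.py` runs
both model variants to their limit cycle and overlays them on an aligned
synthetic cohort (the 1.2× synthesis step reaches only ~20% of the
concentration amplitude the degradation step produces). Small tables land
in `results/`; full trace tables go to `scratch/`.

A `rbdyn` console script exposes the same stages
(`generate`, `process`, `fit`, `classify`, `simulate-model`,
`reproduce-overlay`, `run-all`) for ad-hoc use.

## Documentation

`docs/methods.md` describes the model, the generator's statistical
assumptions, estimator conventions, numerical choices and known
limitations.
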
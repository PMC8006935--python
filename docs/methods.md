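# Methods

This note documents the model, the default parameterization and the
numerical/statistical choices behind `gliomasyn`.

## 1. Model

Four compartments evolve in time `t` (hours):

* `N` — non-cancerous precursor cells,
* `C` — undifferentiated cancer cells,
* `C_R` — drug-resistant cancer subclone,
* `C_S` — drug-sensitive cancer subclone.

Writing `G(α, X) = α·X·ln(K / (X + μ))` for the μ-regularized Gompertz term
(natural logarithm; `G(α, 0) = 0`, sign change where `X + μ` crosses the
shared carrying capacity `K`), the drug-free system is

```
dN/dt   = α_N·N·(1 − ρ)·(1 − N/K) − δ_N·N − α_N·ρ·N
dC/dt   = α_N·ρ·N + G(α_C, C) − (γ_R + ω_S)·α_C·C − δ_C·C
dC_R/dt = γ_R·α_C·C + γ̃_R·α_CS·C_S + G(α_CR, C_R) − δ_R·C_R − ω̃_S·α_CR·C_R
dC_S/dt = ω_S·α_C·C + ω̃_S·α_CR·C_R + G(α_CS, C_S) − δ_S·C_S − γ̃_R·α_CS·C_S
```

`N` grows logistically and feeds `C` by mutation with probability `ρ`; `C`
grows by Gompertz kinetics and differentiates into the two subclones with
`γ_R + ω_S = 1` (enforced at construction: a differentiating cell commits to
exactly one fate). The subclones interconvert, with the resistant-directed
switch dominating (`γ̃_R > ω̃_S`), and die at first-order rates.

### Drug action

Drugs are modelled as constant concentrations over the exposure window.
Drug 1 is temozolomide (TMZ), drug 2 one acridone derivative (AC2, AC7 or
AC26). Each (drug, subclone) pair carries an Emax/Hill triplet, giving
per-capita kill rates

```
k(D) = emax · D^η / (IC50^η + D^η)
```

subtracted from the `C_R` and `C_S` equations only (`k_r = k_TMZ,r + k_ac,r`
and analogously `k_s`; kill terms are additive across drugs — interaction
beyond independence is an *output*, not an input). Because doses are
constant, the treated system is the drug-free system plus constant
per-capita loss rates, which is what the compiled integrator exploits.
`k(IC50) = emax/2` exactly, for any Hill exponent.

## 2. Default parameters

Defaults live in `src/gliomasyn/data/default_params.yaml` (version-controlled
data, not code).

### Pharmacodynamics (72-h exposures, doses in µM)

IC50s on the sensitive/resistant subclones:

| drug | IC50 resistant | IC50 sensitive | η |
| --- | --- | --- | --- |
| TMZ | 190.0 | 23.33 | 2 |
| AC26 | 0.76 | 0.90 | 2 |
| AC2 | 1.53 | 1.53 | 2 |
| AC7 | 1.05 | 5.67 | 2 |

TMZ is ~8× less potent against the resistant clone — this asymmetry is the
resistance phenotype. The acridones keep near-equal potency on both clones,
which is why they are candidate combination partners. Each `emax` (0.05–0.11
per hour) was calibrated once so that the simulated 72-h monotherapy
relative-growth curve of the targeted compartment crosses 50% near the
configured IC50 (self-consistency is asserted in the tests at 15%).

Toxicity bounds cap all dose grids: TMZ ≤ 250 µM, acridones ≤ 100 µM.
Default grid ranges: TMZ 0–200, AC2 0–2, AC7 0–6, AC26 0–6 µM.

### Growth kinetics (per hour unless noted)

`α_N 0.075, δ_N 0.015, ρ 0.01, K 10000 cells, μ 1 cell, α_C 0.045,
δ_C 0.4, γ_R 0.6, ω_S 0.4, α_CR 0.06, δ_R 0.015, ω̃_S 0.25, α_CS 0.0525,
δ_S 0.03, γ̃_R 0.5.`

The set was calibrated once, before the acceptance suite existed, to satisfy
three qualitative study conditions and then frozen:

1. the resistant subclone dominates at drug-free steady state
   (`C_R* ≈ 8093 > C_S* ≈ 5306`);
2. all compartments settle (relative derivative < 1e−6/h) well inside the
   300 h simulation window;
3. the TMZ+AC26 Bliss surface on `C_R` is net-synergistic (below).

### Why the default surface is synergistic

With influx-buffered compartments, Bliss scoring on a single compartment
tends to antagonism: each monotherapy's effect is partly absorbed by
replenishment from upstream pools, so the product of the two single-agent
survivals underestimates the combination's replenishment loss. The defaults
instead put most of the cancer mass in a strongly coupled `C_R ↔ C_S`
interconversion loop fed by a small `C` pool (large `δ_C` keeps `C` small).
Killing `C_S` (mostly TMZ) then removes a growth subsidy of `C_R` at the
same time as the acridone kills `C_R` directly; the combined effect on `C_R`
exceeds the Bliss product of the monotherapy effects, giving negative scores
over the whole interior of the default grid (mean ≈ −0.31 percentage
points).

## 3. Numerics

* **Reference integrator** (`simulate.integrate`): scipy `solve_ivp` RK45
  (Dormand–Prince), `rtol 1e−7`, `atol 1e−9`, sampled every 0.5 h. Tiny
  negative excursions in sampled states are clipped to 0 and counted.
* **Hot-path integrator** (`_fast.py`): numba-jitted classical RK4 with a
  fixed 0.1 h sub-step, used by the MCMC likelihood, LHS-PRCC sweep and the
  dose grids (thousands to hundreds of thousands of solves). States are
  clamped at 0 each step; non-finite values or values above 1e15 signal
  blow-up, which the likelihood maps to −∞. Agreement with the reference
  integrator is asserted in the tests (≤0.1% at 300 h).
* **Steady state**: first sampled time at which every compartment satisfies
  `|dX/dt| / (X + μ) < 1e−6` per hour; if the 300 h cap is hit first, the
  final state is returned with a `SteadyStateWarning`.
* **Horizons**: 72 h fixed exposure for dose-response/IC50 work (matching a
  3-day viability assay); steady state for the synergy surfaces.
* The Hill term is evaluated on the log scale so extreme dose/IC50 ratios
  cannot overflow.

## 4. Inference (DRAM MCMC)

Single-chain Delayed-Rejection Adaptive-Metropolis:

* Gaussian random-walk proposal; after 1000 iterations the covariance is
  refreshed every 100 iterations as `2.38²/d · cov(history) + 1e−10·I`.
* One delayed-rejection stage: a rejected move is retried from the proposal
  shrunk by 0.2, accepted with the standard two-stage ratio (computed with a
  numerically safe `log(1 − exp(·))`), preserving detailed balance.
* Likelihood: independent Gaussians around the deterministic trajectory at
  the observation times, with the dataset's recorded noise SDs.
* Priors: independent truncated normals centred on the defaults
  (sd = 25% of the value, bounds [0.2×, 5×], probabilities capped at 1).
  `ω_S` is derived as `1 − γ_R` whenever `γ_R` is free.
* Chains are bit-reproducible given a seed. Diagnostics: ESS (Geyer initial
  positive sequence), Geweke z, quantiles, degenerate-chain flags.
* Validation: on a correlated 2-D Gaussian the sampler recovers the mean
  within 0.05 sd and covariance entries within 10%; on synthetic growth
  data, 95% credible intervals cover the generating truth for ≥90% of
  (parameter, replicate) pairs across 20 replicate fits.

Synthetic growth data: drug-free trajectories observed at 0–96 h every 4 h
on (`C`, `C_R`, `C_S`), Gaussian noise (default 5% of each trajectory mean)
truncated at zero, with the generating truth and seed recorded in a JSON
sidecar.

## 5. Sensitivity (LHS-PRCC)

Latin hypercube sampling (scipy `qmc.LatinHypercube`: one draw per
equal-probability stratum per parameter) over 28 independent quantities —
14 growth parameters (`ω_S` derived from `γ_R`; sampling both would make the
rank-regression design singular), 12 Emax/Hill parameters and the 2 doses —
each over ±50% of its default (probabilities clipped to [0, 1], acridone
ranges spanning all three derivatives, doses spanning the default grids).
Outputs are the four compartment abundances at 300 h. PRCC is computed by
rank-transforming all columns and correlating the residuals of each
parameter after linear regression on the other ranks; p-values use the t
statistic with `n − 2 − (k − 1)` degrees of freedom. Failed simulations are
dropped (error if >10%). Zero-width ranges pin a parameter and exclude it
from the design.

## 6. Synergy and pharmacology statistics

* **Dose grids**: 100×100 linearly spaced levels including 0, within the
  toxicity bounds. Relative growth is normalized to the grid's own (0, 0)
  corner, which is exactly 100 by construction.
* **Bliss**: with fractional inhibitions `y_A, y_B ∈ [0, 1]` from the grid
  margins, expected combined inhibition is `y_A + y_B − y_A·y_B`. The score
  is `observed growth − expected growth` in percentage points, so
  **negative = synergy**; zero-dose margins score exactly 0.
* **IC50 from curves**: log-dose linear interpolation at the 50% growth
  crossing (zero doses excluded; first bracketing pair); a curve that never
  crosses raises an error carrying the maximal observed inhibition.
* **Selectivity index** `SI = CC50(Vero) / IC50(tumor)`, two decimals:
  TMZ 482/23.33 = 20.66, AC26 66.08/0.90 = 73.42.
* **Fold change** of an IC50 under combination: ratio `final/initial` and
  percent `|final − initial|/initial·100`, two decimals (e.g. TMZ with AC26:
  190 → 102.3 µM, 0.54×; AC26 with TMZ: 0.76 → 0.67, 0.88×/11.84%; TMZ with
  AC7: 190 → 46.2, 0.24×/75.68%).
* **Combination index** `CI = d₁/IC50₁ + d₂/IC50₂` (mutually nonexclusive
  Chou–Talalay form without the interaction term); < 0.8 synergism, 0.8–1.2
  additive, > 1.2 antagonism.

## 7. Limitations

* Doses are constant over the exposure window — no pharmacokinetics, decay
  or scheduling; combination timing effects are out of scope.
* The Gaussian observation model assumes known, homoskedastic-per-compartment
  noise; inferring the noise level is not implemented.
* Bliss scores are computed per compartment; organism-level endpoints
  (total burden, survival) would need a different readout.
* The default growth parameterization is a calibrated in-silico study
  condition, not a fit to a specific cell line; quantitative outputs (e.g.
  the −0.31 mean synergy score) are parameterization-dependent, while the
  qualitative claims (resistant dominance, net synergy of TMZ+AC26 on `C_R`)
  are the tested invariants.
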
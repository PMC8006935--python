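# gliomasyn

In-silico screening of temozolomide (TMZ) + acridone-derivative combinations
against drug-resistant glioma.

Glioblastoma therapy routinely fails because a drug-resistant subclone
survives TMZ monotherapy and regrows the tumor. `gliomasyn` implements a
four-compartment ordinary-differential-equation model of a heterogeneous
glioma — non-cancerous precursors (`N`), undifferentiated cancer cells (`C`)
and interconverting drug-resistant (`C_R`) / drug-sensitive (`C_S`)
subclones — and uses it to screen two-drug dose combinations. Drug action
enters as saturating Emax/Hill kill terms on the two subclones; combinations
of TMZ with one of three acridone derivatives (AC2, AC7, AC26) are scored
over 100×100 dose grids against the Bliss-independence expectation. The
package also provides Bayesian parameter inference (DRAM MCMC), global
sensitivity analysis (LHS-PRCC) and standard pharmacology statistics
(IC50 interpolation, selectivity index, combination index, fold change).

See [docs/methods.md](docs/methods.md) for the model equations, parameter
tables and numerical choices.

## Package layout

| module | contents |
| --- | --- |
| `gliomasyn.model_core` | state/parameter dataclasses, Gompertz and Emax/Hill terms, drug-free and treated right-hand sides |
| `gliomasyn.simulate` | adaptive RK45 integration, steady-state detection, relative-growth readouts, compiled fast endpoint |
| `gliomasyn.synthetic_data` | noisy growth-curve and dose-response generators with recorded truth |
| `gliomasyn.inference` | truncated-normal priors, Gaussian likelihood, DRAM sampler, chain diagnostics, posterior predictive |
| `gliomasyn.sensitivity` | Latin-hypercube sampling and partial rank correlation coefficients over 28 varied quantities |
| `gliomasyn.synergy_pharm` | dose grids, Bliss synergy surfaces, IC50/SI/CI/fold-change statistics |
| `gliomasyn.cli_io` | `gliomasyn` command-line interface, pipeline orchestration, provenance sidecars |

## Quick start

```python
import numpy as np
from gliomasyn.defaults import (default_growth_params, default_drug_params,
                                default_initial_state)
from gliomasyn.simulate import steady_state
from gliomasyn.synergy_pharm import DoseGrid, dose_response_matrix, synergy_surface

p = default_growth_params()
dp = default_drug_params("AC26")
s0 = default_initial_state()

ss = steady_state(s0, p)          # drug-free equilibrium
print(ss.c_r, ss.c_s)             # resistant subclone dominates

grid = DoseGrid.default("AC26", n=100)          # TMZ 0-200 uM x AC26 0-6 uM
mat = dose_response_matrix(p, dp, grid, compartment="C_R",
                           horizon="steady_state")
surf = synergy_surface(mat)       # negative scores = synergy
print(surf.mean_interior_score())
```

Printed output under the packaged defaults:

```
8093.186394266819 5305.803959159718
-0.31051516862914064
```

i.e. the resistant clone outnumbers the sensitive one at equilibrium and the
TMZ+AC26 combination is on average synergistic (Bliss score −0.31 percentage
points over the 99×99 interior dose pairs, all interior scores ≤ 0).

Command line equivalents:

```bash
gliomasyn --seed 1 --out results synergy --drug AC26
gliomasyn --seed 1 --out results report     # full pipeline, all artifacts
```

`report` runs synthetic-data generation → DRAM fit → trajectory simulation →
dose grid → synergy surface → LHS-PRCC, writing CSVs plus a
`provenance.json` recording the config hash and stage seeds. Reruns with the
same config are byte-identical.

## Pharmacology statistics

```python
from gliomasyn.synergy_pharm import selectivity_index, fold_change, combination_index

selectivity_index(482.0, 23.33)   # 20.66  (TMZ: CC50 Vero / IC50 U87)
selectivity_index(66.08, 0.9)     # 73.42  (AC26)
fold_change(190.0, 102.3)         # (0.54, 46.16)  TMZ IC50 shift with AC26
combination_index(36.3, 1.48, 190.0, 1.53)  # (1.158..., 'additive')
```

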
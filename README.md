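# tauseed

Network transport modelling of early tau seeding on structural brain
connectomes, for researchers studying why tau pathology in Alzheimer's
disease and primary age-related tauopathy begins in the entorhinal cortex.

The package implements an **anomaly-weighted Laplacian transport model**:
tau seeds are produced, degraded and carried along white-matter connections,
and a per-region "anomaly level" `A_i` — regional neuronal activity (FDG
PET SUVR) or amyloid-β burden (amyloid PET SUVR) — multiplicatively scales
outgoing transport:

```
du_i/dt = -ρ Σ_j L_ij (1 + ε A_j) u_j + k − λ u_i
```

with `L` the graph Laplacian of the connectome
(`L_ij = −W_ij + δ_ij Σ_k W_kj`), `ρ` the transport coefficient, `k` the
production rate and `λ` the degradation rate.  In the transport-dominated
regime the stationary concentration in region *i* scales as
`1/(1 + ε A_i)` regardless of topology, so **low-activity (or
amyloid-spared) regions surrounded by high-anomaly neighbours accumulate
seeds** — a mechanistic account of entorhinal vulnerability.

Around the model the package provides:

- a bundled 84-region Desikan-Killiany-style atlas with Braak-stage
  membership, amyloid/tau positivity composites and the unstable-region
  correction map (`tauseed.atlas`);
- connectome construction (symmetrize, normalize by maximum, cutoff
  filter, connectivity validation) and CSV I/O (`tauseed.connectome`);
- PET cohort handling: SUVR tables, the unstable-region SUVR correction,
  positivity thresholds (amyloid > 1.11, tau MTL > 1.375, tau
  neocortical > 1.395), biomarker-group stratification and ±12-month
  cross-modality scan pairing (`tauseed.pet`);
- permutation inference: regional-shuffle null, largest-gap seeding
  threshold, Braak-stage seed-count tests with permutation p and z
  (`tauseed.inference`);
- cohort statistics: subject-level seeding predictions, Welch contrasts
  with Bonferroni adjustment, simple/adjusted/stratified OLS with
  standardized effects, marginal-effect lines, bootstrap power
  (`tauseed.stats`);
- a synthetic cohort generator with `PART_like` and `AD_like` scenario
  presets and exact regression ground truth (`tauseed.synthetic`);
- an end-to-end pipeline and a `tauseed` command-line interface
  (`tauseed.pipeline`, `tauseed.cli`).

## Worked example

Fit the model to the all-subject mean activity pattern of the `PART_like`
synthetic scenario and test whether the entorhinal cortex is seeded more
often than chance:

```python
import numpy as np
import tauseed as ts
from tauseed.synthetic import get_preset, synth_connectome

cfg = get_preset("PART_like", rng_seed=1)
atlas = ts.default_atlas()
conn = synth_connectome(cfg, atlas)
pattern = np.mean([cfg.group_means[g]["FDG"] for g in cfg.group_means], axis=0)
field = ts.AnomalyField(atlas=atlas, values=pattern, modality="FDG",
                        provenance="group_average")

print(ts.TauTransportModel(conn, field).fit().summary())
print(ts.SeedingPermutationTest(conn, field).fit(n_perm=10_000, rng_seed=7).summary())
```

prints

```
Anomaly-weighted transport model — stationary solution
  regions: 84   modality: FDG
  epsilon=5.0 rho=1.0 k=0.02 lam=0.2
  residual (max-norm): 4.458e-15
  total mass: 8.400000 (N*k/lam = 8.400000)
  top regions by stationary concentration:
    entorhinal-L                 0.187391
    entorhinal-R                 0.182620
    amygdala-R                   0.130503
    parahippocampal-L            0.129137
    lingual-L                    0.127882
    parahippocampal-R            0.126635

Seeding permutation test
  permutations: 10000
  seeding threshold: 0.156372
  seeded regions (2): entorhinal-L, entorhinal-R
  braak1: observed 2/2  p = 0.0004  z = 9.46
  braak1_3: observed 2/12  p = 0.0181  z = 3.52
```

The stationary solution concentrates tau seeds in the medial temporal lobe
(total mass is the exact production/degradation balance `N·k/λ`); both
entorhinal regions exceed the null-derived seeding threshold, and the
permutation test shows that randomly shuffled activity patterns almost
never seed Braak stage 1 (`p ≈ 4·10⁻⁴`).

The same analysis runs end to end — stratification, group contrasts and
regressions included — via

```bash
tauseed run --preset PART_like --n-perm 10000 --seed 1 --out-dir out/
tauseed synth --preset AD_like --seed 11 --out-dir data/   # CSVs + manifest
```

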
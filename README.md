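# hierfixel

Hierarchical crossing-fibre modelling of diffusion MRI, with fixel-based
statistics.

## The problem

Diffusion MRI studies routinely compare white-matter microstructure across
subjects. Voxel-wise summaries (FA, MD) conflate the several fibre
populations that cross inside most white-matter voxels, so *fixel-based*
analysis assigns metrics to each fibre population (a **fixel** = one fibre
orientation within one voxel) instead. The catch: fixels estimated
independently in each subject must afterwards be matched across subjects,
and this post-hoc relabelling fails exactly where it matters — noisy
subjects, weak secondary fibres, near-parallel crossings.

`hierfixel` removes the matching step by fitting a *population-level*
crossing-fibre model. In every voxel, each subject's ball-and-sticks
parameters are treated as draws from a group distribution — Gaussian for
scalars, Watson for stick orientations:

```
S(b, g) = S0 [ Σᵢ fᵢ e^{−b d (μᵢᵀg)²} + (1 − Σᵢ fᵢ) e^{−b d} ]

νₛ ~ Normal(ν_g, σ_g²)          (scalar parameters)
μₛ ~ Watson(μ_g, κ_g)           (stick axes; ODI = (2/π) arctan 1/κ)
Dₛ ~ Normal(M(νₛ), σₛ² I)       (measured signal)
```

Because subject stick *i* is tied to group stick *i* by its prior, fibre
labels are consistent across subjects **by construction**. The joint MAP
problem is solved by an EM-style alternation: closed-form group updates
(scalars) and Watson fits (orientations) with subjects fixed, then
independent per-subject MAP re-fits with the group fixed. The converged
group parameters form a **fixel template** that can later be used as a
prior to fit new subjects at the cost of an ordinary single-subject fit.

Downstream, per-fixel metrics are analysed with a GLM, and familywise
error across fixels is controlled by threshold-free cluster enhancement
(TFCE) generalised to a fixel graph — fixels in 27-neighbouring voxels
with axial angle below a threshold are neighbours — with max-statistic
permutation inference.

Intended users: diffusion-MRI methods researchers and analysts running
fibre-specific group studies.

## Worked example

Simulate the package's reference cohort — 30 subjects, one voxel with two
crossing fibre populations (signal fractions drawn around 0.5/0.3 and
renormalised to sum to 0.8, per-fibre orientation scatter ODI = 0.1, 55
two-shell volumes, SNR 50) — and fit the two-fibre hierarchical model:

```python
import numpy as np
from hierfixel import PopulationSpec, EMConfig, simulate_population, run_em

spec = PopulationSpec(seed=42)          # 30 subjects, one crossing-fibre voxel
signals, truth = simulate_population(spec)

pop, fits, diag = run_em(signals, spec.scheme, n_fibres=2, cfg=EMConfig(seed=7))

print("converged:", diag["converged"], "after", diag["n_iter"], "iterations")
print("group mean fractions:", np.round(pop.mean_fractions, 4))
print("true sample means:   ", np.round(truth.fractions().mean(axis=0), 4))
print("group ODI per fibre: ", [round(w.odi, 4) for w in pop.orient_pops])
```

prints

```
converged: True after 21 iterations
group mean fractions: [0.5095 0.289 ]
true sample means:    [0.5141 0.2859]
group ODI per fibre:  [0.0952, 0.0765]
```

The fitted group mean fractions land within a few thousandths of this
cohort's true sample means, and the recovered cross-subject orientation
dispersion is close to the generating ODI of 0.1 (the second, weaker fibre
shows the mild shrinkage expected from its orientation prior). `fits`
holds the per-subject parameters with stick 1 referring to the *same*
fibre population in every subject.

## Command-line pipeline

The same machinery drives a four-stage shell pipeline:

```bash
hierfixel simulate cohort/ --preset phantom --with-warps --n-subjects 8
hierfixel fit-template cohort/manifest.tsv template/ --mask cohort/mask.nii.gz
hierfixel fit-subject sub_dwi.nii.gz sub.bval sub.bvec template/ fixels_sub/ --warp sub_warp.nii.gz
hierfixel glm-tfce design.tsv stats/ fixels_sub-*/ --contrast age --n-perm 5000
```

`fit-template` chooses the per-voxel fibre count (1–3) by thresholding the
cohort-summed log-likelihood gain of adding a stick, and writes a template
directory of NIfTI maps (fibre count, parameter means/variances, per-fibre
axes and dispersions) plus a JSON sidecar. `fit-subject` consumes the
template as a prior (orientation priors only, by default) and emits a
fixel directory; `glm-tfce` runs the per-fixel GLM, fixel TFCE and
permutation familywise correction. Every output directory contains a
provenance JSON (config, seed, versions).

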
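# fwdti-glioma

Multi-shell free-water elimination DTI for tumor sub-region
characterization, with a ground-truth synthetic phantom.

Diffusion tensor metrics inside and around brain tumors are biased by
freely diffusing water — vasogenic edema, cystic fluid, necrosis, CSF. This
package separates that contribution with the two-compartment (bi-tensor)
model

    S_k = s0 · [ f · e^(−b_k d_fw) + (1 − f) · e^(−b_k ĝ_kᵀ D ĝ_k) ],

where `f` is the per-voxel fractional volume of the free-water (FW)
compartment with fixed isotropic diffusivity `d_fw = 3.0·10⁻³ mm²/s`, and
`D` is the tissue tensor whose fractional anisotropy (**FAt**) is the
FW-corrected counterpart of conventional single-shell **FA**. The fit is a
spatially regularized, monotone projected Gauss–Newton descent on
multi-shell data (see `docs/methods.md` for the full model, numerics and
design choices).

Intended users: researchers in quantitative diffusion MRI who want a
tested, self-contained reference implementation of FW elimination plus the
downstream tumor-region analysis (ROI histogram radiomics, paired
statistics, voxel-wise ROC), runnable end to end without any clinical data.

## What's inside

| module | contents |
| --- | --- |
| `fwdti.gradients_io` | NIfTI I/O, FSL `bval`/`bvec` parsing, shell grouping |
| `fwdti.phantom` | synthetic multi-shell tumor phantom with ground truth |
| `fwdti.dti` | single-shell OLS tensor fit, eigen-decomposition, FA/MD |
| `fwdti.fwe` | the regularized two-compartment free-water fit |
| `fwdti.roi_stats` | ROI mask algebra and 8 histogram summary variables |
| `fwdti.group_stats` | paired t / Bonferroni / ANOVA + Tukey / logistic ROC |
| `fwdti.pipeline`, `fwdti.cli` | study orchestration and the `fwdti` CLI |

## Worked example

Simulate one noisy subject, fit the free-water model, and summarize the FW
map per tumor sub-region:

```python
import numpy as np
from fwdti import PhantomSpec, FitConfig, generate_phantom, fit_fwe, roi_summary
from fwdti.fwe import default_alpha

spec = PhantomSpec(snr=30.0, seed=1)          # default 48x48x12 tumor slab
dwi, scheme, masks, truth = generate_phantom(spec)
res = fit_fwe(dwi, scheme, config=FitConfig(alpha=default_alpha(len(scheme))))

for region in ("necrotic", "enhancing", "non_enhancing"):
    stats = roi_summary(res.f, masks.region(region))
    print(f"{region:>14}: FW mean {stats.mean:.3f}  sd {np.sqrt(stats.variance):.3f}  "
          f"entropy {stats.entropy:.2f} bits  (n={stats.n_voxels})")
lesion = masks.total & res.fit_mask
print(f"lesion f RMSE vs truth: {np.sqrt(np.mean((res.f[lesion]-truth.f_true[lesion])**2)):.3f}")
```

prints

```
      necrotic: FW mean 0.617  sd 0.132  entropy 5.69 bits  (n=81)
     enhancing: FW mean 0.323  sd 0.106  entropy 6.50 bits  (n=402)
 non_enhancing: FW mean 0.311  sd 0.106  entropy 6.69 bits  (n=1228)
lesion f RMSE vs truth: 0.046
```

The presumed-necrotic core shows the highest free-water content with the
largest spread (it was planted at f ≈ 0.50 ± 0.15; the slight upward shift
is Rician noise bias), the rest of the lesion sits near f ≈ 0.30, and the
voxel-wise error of the fitted FW fraction against the planted truth is
below 0.05 at SNR 30.

A whole synthetic study — 10 high-grade and 6 low-grade subjects, both fits
per subject, summary tables, paired FA-vs-FAt tests with Bonferroni
adjustment, ANOVA + Tukey across regions, per-subject ROC — runs from the
shell:

```sh
fwdti run-all --out study/ --seed 1
```

and writes `summaries.csv`, `stats_tests.csv`, `roc.csv` and a markdown
`report.md`. The staged subcommands (`simulate`, `fit`, `summarize`,
`stats`, `roc`, `report`) operate on directories of NIfTI volumes with FSL
gradient tables, so any dataset following that file contract can be pushed
through the same path.

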
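# mfcparc

Dual-modality, connectivity-based parcellation of a cortical seed region.

Cortical sub-regions can be delineated by their *connectional
fingerprints*: the pattern of each vertex's connectivity to the rest of
the brain. `mfcparc` implements that idea for two kinds of connectivity
over the same seed region (the motivating case is the medial frontal
cortex and its SMA / pre-SMA split):

* **functional** — Pearson correlation between resting-state fMRI time
  series of a seed vertex and every other cerebral vertex, computed per
  subject, Fisher r-to-z transformed and summed over subjects;
* **structural covariance** — Pearson correlation *across subjects*
  between cortical thickness at a seed vertex and at every other vertex,
  one group-level matrix.

Either modality yields an `Ns × Nw` seed-correlation matrix `C` with
`C(i,j) = COV(X_i, X_j) / (σ_i σ_j)` (then `z = arctanh r`), whose rows
are the fingerprints. Seed vertices are clustered by those rows with

* **Ward's minimum-variance** agglomeration on the raw rows, and
* **normalised spectral clustering** of the affinity
  `A_ij = (corr(row_i, row_j) + 1) / 2`.

The number of clusters is selected with split-half **variation of
information** (`VI = H(P) + H(Q) − 2 I(P,Q)`, 100 random subject splits)
and the per-subject mean **silhouette**; cross-modal agreement is scored
with matched **dice coefficients** (`2|A∩B| / (|A|+|B|)` after Hungarian
label matching); inter-subject reliability uses 5-fold × 30-repeat
resampling of the group matrix. Finally, each sub-region serves as a seed
for whole-brain network statistics over an atlas of target regions:
one-sample right-tailed t-tests on per-subject Fisher-z values with
Benjamini–Hochberg FDR (functional), or a group z > 0.4 threshold with
the null `z ~ N(0, 1/√(n−3))` (thickness).

Because real cohorts of this kind cannot be redistributed, the package
ships a first-class synthetic-cohort generator: K planted seed clusters
with distinct fingerprints to M target modules, expressed through shared
latent time courses (fMRI) or shared cross-subject latent factors
(thickness), plus i.i.d. Gaussian noise and jittered per-subject ROI
masks. Every stage of the pipeline is tested against that ground truth.

## Worked example

```python
import numpy as np
from mfcparc import CohortConfig, ParcellationModel, generate_cohort

cohort = generate_cohort(CohortConfig(rng_seed=7))   # 40 subjects, K = 2

model = ParcellationModel.from_cohort(cohort, modality="fmri", algorithm="ward")
res = model.fit(k=2)
print(res.summary())

thick = ParcellationModel.from_cohort(cohort, modality="thickness", algorithm="ward")
dice = res.compare(thick.fit(k=2))
print(f"\ncross-modal dice: {dice.mean_dice:.3f}")

sel, vi, sil = model.select_k(k_values=range(2, 7), n_repeats=50, rng_seed=0)
print(f"selected k: {sel.k} (VI plateau: {sel.vi_plateau_k})")
print("mean silhouette by k:", np.round(sil.mean_silhouette, 3))
```

prints

```
Connectivity-based parcellation
================================================
modality:         fmri
algorithm:        ward
seed vertices:    120
target vertices:  400
subjects:         40
clusters (k):     2
cluster sizes:    1: 60, 2: 60
mean silhouette:  0.9902

cross-modal dice: 1.000
selected k: 2 (VI plateau: None)
mean silhouette by k: [0.937 0.567 0.193 0.162 0.143]
```

The two planted sub-regions are recovered exactly from the functional
matrix (60 + 60 vertices, silhouette 0.99), the thickness-driven
parcellation agrees perfectly with it (mean dice 1.0), and model
selection puts the silhouette maximum at k = 2 while the VI curve keeps
rising significantly with k, so no VI plateau exists — the silhouette
argmax decides.

The same workflow is available from the shell:

```bash
mfcparc simulate --out cohort --rng-seed 7
mfcparc roi --cohort cohort --out roi.tsv            # 75% probabilistic ROI
mfcparc connect --cohort cohort --roi roi.tsv --out corr.tsv
mfcparc parcellate --matrix corr.tsv --k 2 --out parc.tsv
mfcparc run-all --out run --rng-seed 7               # the whole pipeline
```

All interchange formats are headered TSV plus JSON sidecars; GIFTI
per-vertex files and NIfTI volumes can be read into the same vertex-table
representation.

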
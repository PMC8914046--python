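# rvstrain

3D right-ventricular (RV) strain quantification from endocardial surface
meshes, with the downstream prognostic toolchain used in clinical outcome
studies: composite cardiac endpoints, Kaplan–Meier / log-rank / Cox analyses,
nested-model likelihood-ratio tests, number-needed-to-treat effect sizes, and
log-rank survival trees for risk stratification. Synthetic mesh-cycle and
cohort generators with analytic ground truth make every stage verifiable
without patient data.

## Who this is for

Researchers in 3D echocardiographic RV quantification who have per-frame
closed endocardial meshes (e.g. exported by speckle-tracking software as a
Wavefront OBJ series over one cardiac cycle) and want volumes, ejection
fraction and the three global strains — and anyone building or validating the
survival-analysis pipeline that typically follows (cohort tables with
follow-up and event types).

## The quantities computed

Given a topology-constant mesh series with end-diastolic (ED) and
end-systolic (ES) frames defined by the volume-curve extrema:

- **RVEF** = (EDV − ESV) / EDV × 100, with volumes from the signed-tetrahedron
  sum over the closed surface;
- **GCS** (global circumferential strain): 15 closed *latitude* contours are
  cut on the ED mesh by planes orthogonal to the long axis at equal spacings
  k/16 between apex and base, then tracked materially (fixed barycentric
  coordinates on fixed faces) through the cycle;
  GCS = mean₍k₎ (C_k^ED − C_k^ES)/C_k^ED × 100;
- **GLS** (global longitudinal strain): 45 apex → mid-cavity → base
  *longitude* contours, realised as shortest paths on the mesh edge graph
  with base seeds at equal azimuthal increments around the basal rim;
  GLS = mean₍j₎ (L_j^ED − L_j^ES)/L_j^ED × 100;
- **GAS** (global area strain): (A^ED − A^ES)/A^ED × 100 over the total
  endocardial surface area.

Shortening is reported as a positive percentage. Under a uniform scaling `s`
of the whole surface the outputs obey the similarity identities
GCS = GLS = (1−s)·100, GAS = (1−s²)·100, RVEF = (1−s³)·100.

## Worked example

Generate a synthetic RV-like cycle with known end-systolic axis scales
(circumferential 0.90, longitudinal 0.85) and run the strain engine:

```python
from rvstrain import compute_strains
from rvstrain.synthetic import MeshCycleParams, generate_mesh_cycle

series, truth = generate_mesh_cycle(MeshCycleParams())
res = compute_strains(series)
print(f"EF  {res.rvef_pct:.2f}%  (truth {truth.ef_pct:.2f}%)")
print(f"GCS {res.gcs_pct:.2f}%  (truth {truth.gcs_pct:.2f}%)")
print(f"GLS {res.gls_pct:.2f}%  (truth {truth.gls_pct:.2f}%)")
print(f"GAS {res.gas_pct:.2f}%  (truth {truth.gas_pct:.2f}%)")
```

prints

```
EF  31.15%  (truth 31.15%)
GCS 10.00%  (truth 10.00%)
GLS 14.02%  (truth 14.01%)
GAS 22.29%  (truth 22.29%)
```

The ground truth comes from quadrature on the continuous surface: the
circumferential contours are horizontal planar curves, so they shorten by
exactly 1 − 0.90 = 10%; meridians mix both scales (≈14%); the cavity volume
shrinks by exactly 1 − 0.90²·0.85 = 31.15%.

The same works from the shell on an OBJ directory:

```bash
rvstrain simulate-mesh --seed 1 --out meshes/
rvstrain strain --mesh-dir meshes/ --out strain.json
rvstrain simulate-cohort --n 341 --seed 1 --out cohort.csv
rvstrain survival --cohort cohort.csv --out fits.json
rvstrain cart --cohort cohort.csv --out tree.json
rvstrain run-all --out-dir demo/      # full pipeline + markdown report
```

The cohort generator draws covariates from a Gaussian copula whose
skew-normal marginals and rank correlations are calibrated to a published
mixed cardiac-disease cohort (n = 341; e.g. median 3D RVEF 47%, RVEF–GAS
Spearman r = 0.93), and plants a configurable Cox hazard on top — so fits,
trees and reports can be validated against known truth.

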
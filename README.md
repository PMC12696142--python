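# fwetract

Free-water-elimination (FWE) tractometry of peritumoral white matter in
diffuse glioma.

Diffuse gliomas alter white matter both by direct invasion and at a distance
from the radiologically visible tumor. Conventional DTI metrics are
confounded there by vasogenic edema: the isotropic free-water signal of
edema masks the underlying tissue microstructure. This package implements,
as a reusable and tested pipeline, an analysis that

1. fits a **single-shell bi-tensor free-water model** to separate tissue
   diffusion from free-water contamination, yielding free-water-corrected
   fractional anisotropy (FW-FA), mean diffusivity (FW-MD) and the
   free-water fraction (FWF);
2. samples those metrics along white-matter tracts at **100 equidistant
   nodes** per bundle (tract profiles) and scores each node's overlap with
   the tumor compartments (enhancing tumor, necrotic core, edema);
3. quantifies **direct tumor involvement** (a node is involved when tumor
   occupies more than 5% of its spatial extent; subject-level binarization,
   tract-level proportions, 1–15% threshold sensitivity sweep);
4. measures **hemispheric asymmetry beyond the tumor margins** at paired
   homologous nodes with < 5% combined tumor involvement,

   `A(%) = (ipsilateral − contralateral) / ((ipsilateral + contralateral)/2) × 100`,

   collapsed per tract and per subject, and resolved by along-tract node
   distance from the tumor edge (segments 1–5, 6–10, 11–15, 16–20, ≥ 21
   nodes);
5. runs the **group inference layer**: Kruskal–Wallis, pairwise
   Mann–Whitney U, Shapiro–Wilk screening, Spearman correlation,
   dummy-coded linear/logistic regression (glioblastoma reference), and
   Benjamini–Hochberg FDR stratified by test family.

Because the real clinical dataset is large and external, the package ships a
**synthetic phantom cohort** generator that emulates the study's structure —
three pathology groups (glioblastoma, astrocytoma, oligodendroglioma),
nested tumor compartments of group-dependent size, bilateral mirror-image
bundles, metric fields with pathology-specific asymmetry gradients that
decay with distance from the tumor margin, and bi-tensor DWI signals with
Rician noise — so every stage runs end-to-end with no download.

It is intended for researchers in diffusion MRI / neuro-oncology imaging who
want to apply or scrutinize FWE tractometry; real data enter as NIfTI
volumes + bvals/bvecs, BraTS-style segmentations and TRK/TCK bundles (or
precomputed profile CSVs).

## Worked example

```bash
fwetract run --out ws --seed 1 --sweep 1:15
```

generates the default 30-subject phantom cohort, profiles it, and writes the
analysis tables under `ws/analysis/` plus a distance-binned asymmetry
figure. The same in Python:

```python
from fwetract import CohortConfig, generate_cohort
from fwetract import analysis

records, manifest = generate_cohort(CohortConfig(seed=1))
asym = analysis.cohort_asymmetry_table(records)
fa = asym[(asym.level == "distance-segment") & (asym.metric == "fw_fa")]
print(fa.groupby(["pathology", "segment"])["asymmetry_pct"].mean()
        .unstack()[["1–5", "6–10", "11–15", "16–20", "≥21"]].round(2))
```

prints (group-mean FW-FA asymmetry in percent by distance from the tumor
margin):

```
segment             1–5  6–10  11–15  16–20   ≥21
pathology
astrocytoma       -0.75 -0.39  -0.31   0.01 -0.11
glioblastoma      -1.55 -0.80  -0.32  -0.08 -0.09
oligodendroglioma  1.59  0.87   0.27   0.08  0.08
```

Read: in the five nodes nearest the tumor margin, glioblastoma and
astrocytoma phantoms show *lower* FW-FA on the tumor side (negative
asymmetry, i.e. degraded microstructure), oligodendroglioma *higher*
(positive asymmetry), and the effect fades with distance — the injected
structure, recovered through the full profiling + asymmetry pipeline.

## Layout

- `src/fwetract/synthetic.py` — phantom cohort generator (the study
  conditions live in `CohortConfig`)
- `src/fwetract/fwe.py` — single-shell bi-tensor free-water fit
- `src/fwetract/tractometry.py` — node resampling, profile sampling,
  involvement scoring
- `src/fwetract/stats.py` — involvement summaries, percent asymmetry,
  distance-to-margin, distance-binned collapse
- `src/fwetract/inference.py`, `src/fwetract/analysis.py` — group tests,
  family-stratified FDR, cohort tables
- `src/fwetract/io.py`, `pipeline.py`, `cli.py` — formats, stage driver,
  CLI

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
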
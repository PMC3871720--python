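# lactoscan

Quantification of milk fat globules, cytoplasmic crescents and nucleated
cells in acridine-orange-stained whole-milk micrographs.

## The problem

Milk carries RNA in two compartments. When a mammary epithelial cell
secretes a fat globule, a sliver of cytoplasm — a **cytoplasmic crescent** —
can be pinched off between the membrane bilayers wrapping the globule; it
contains RNA but no nucleus. Milk also contains **nucleated somatic cells**
(immune and epithelial), which carry both RNA and DNA. Anyone using milk as
a non-invasive window on mammary gene expression needs to know how much of
the milk RNA is cellular and how much is crescent-derived ("exosomal").

Acridine orange (AO) separates the two optically: bound to RNA it emits at
~650 nm (red), bound to DNA at ~525 nm (green). A three-channel micrograph
— differential interference contrast (DIC) to see the globules as gray
bubbles, plus the AO-RNA and AO-DNA fluorescence planes — therefore shows
crescents as RNA-only objects hugging globule boundaries and cells as
colocalized RNA+DNA objects.

## What the package computes

For each image (optionally tiled, for whole-slide scans):

1. **Globules** are segmented in the DIC plane (gradient-magnitude
   threshold → morphological closing → hole filling, since DIC renders rims
   rather than filled disks), then filtered by area and circularity
   4πA/P².
2. **RNA objects** are segmented in the AO-RNA plane (Gaussian smoothing →
   global threshold → 8-connected components) and classified by overlap
   with the dilated AO-DNA mask: overlap fraction ≥ 0.3 → nucleated cell,
   otherwise crescent candidate.
3. Each crescent is **linked** to the globule minimizing
   ‖c − g‖₂ − r_g (centroid-to-boundary distance), ties to the lowest
   globule id, orphaned beyond 25 px.
4. Per-image **summary statistics**:
   - crescent incidence = 100 · (#globules with ≥ 1 linked crescent) / #globules
   - cellular RNA % = 100 · Σ_cells I / (Σ_cells I + Σ_crescents I), with
     I the background-subtracted integrated AO-RNA intensity (or object
     area in `area` mode); exosomal RNA % is the complement.

A synthetic-scene generator (`lactoscan.synthetic`) renders AO-milk fields
with exact per-object ground truth — lognormal globules, boundary-hugging
crescent arcs, free cells, blur, and noise — so the whole pipeline is
testable without any real micrograph. Experiment-level statistics
(Welch's t-test, √n-width boxplot summaries, OLS fits) live in
`lactoscan.stats`.

## Worked example

```python
import lactoscan as ls

scene = ls.generate_scene(ls.SceneParams(seed=1))     # 512x512, 200 globules
stack = ls.render_channels(scene)                     # DIC + AO-RNA + AO-DNA
result = ls.process_stack(stack)
s = result.summary
print(f"globules={s.n_globules}  crescents={s.n_crescents}  cells={s.n_cells}")
print(f"incidence={s.pct_globules_with_crescents:.2f}%  "
      f"cellular RNA={s.cellular_rna_pct:.2f}%  (truth {100*scene.cellular_share:.2f}%)")
```

prints

```
globules=200  crescents=12  cells=10
incidence=6.00%  cellular RNA=54.73%  (truth 54.61%)
```

All 200 globules and all 12 crescents are recovered, so the incidence
equals the configured 6 % exactly; the intensity-weighted cellular share is
recovered within 0.2 percentage points of the generator's ground truth.

The same pipeline is scriptable from the shell:

```sh
lactoscan simulate --seed 3 --out sim/            # TIFF + ground-truth CSV
lactoscan quantify sim/*.tif --out results/       # summary.csv, objects.csv, manifest.json
lactoscan compare results/summary.csv --group-col group --out comparisons.csv
```

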
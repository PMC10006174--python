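# pixplore

Segmentation-free, pixel-level phenotyping of imaging mass cytometry
(IMC) images.

IMC rasterizes a stained tissue section at ~1 µm per pixel with one
intensity channel per metal-tagged antibody (CD45, CD3, CD7, CD20,
HLA-DR, CD163, E-cadherin, …). Instead of segmenting cells first,
pixplore classifies **pixels** directly — robust in dense structures such
as lymphoid follicles where segmentation is unreliable — and projects the
classes back onto the tissue raster. It is written for computational
biologists analyzing multiplexed tissue images who need a scriptable,
reproducible alternative to interactive pixel-gating tools.

The pipeline:

1. **Preprocess** — clip each channel at its 98th-percentile
   maximum-signal threshold, transform with `asinh(x/5)`, and flatten to
   an N×M pixels-by-markers table.
2. **Hierarchy** — build an HSNE-style multi-scale landmark hierarchy:
   random walks on the kNN graph select landmarks (visit count > 1.5×
   expectation), absorbing walks give each landmark a row-stochastic
   *area of influence* over finer points, and landmark weights conserve
   the pixel count. Scales of a 2.5×10⁵-pixel ROI reduce roughly
   250 000 → 50 000 → 10 000.
3. **Embed & gate** — weighted exact-gradient t-SNE of any scale,
   weighted Gaussian mean-shift clustering of the embedding, drill-down
   into selected landmarks, expansion of cluster labels to all pixels via
   argmax influence, and cell-type naming against marker signatures
   (e.g. T cell CD3⁺CD7⁺, ILC CD3⁻CD7⁺, B cell CD20⁺HLA-DR⁺).
4. **Render** — back-project up to 9 classes with unique colors at the
   original 1 px = 1 µm raster.
5. **Quantify** — count double-positive pixels (e.g. CD161⁺CD69⁺) inside
   annotated regions and compare region groups (lymphoid follicles vs
   matched non-follicle areas) with a one-tailed Mann–Whitney U test,
   exact by full enumeration for small designs (n₁+n₂ ≤ 20, no ties).

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

The bundled synthetic demo builds a follicle scene (96×96 px, epithelium
band, stromal lamina propria with scattered immune cells, one lymphoid
follicle disc and one control disc), then runs the full pipeline:

```bash
pixplore run --demo --out demo --seed 0
```

or in Python:

```python
import pixplore as px
cfg = px.write_demo_inputs("demo", seed=0)
artifacts = px.run_pipeline(cfg)
```

This writes, under `demo/results/`, the pixel table, the hierarchy
container, the top-scale embedding, a label map with its class names, the
colored overlay, and `quantification.tsv`:

```
region	group	positive_count	total_count	fraction
LF1	LF	193	805	0.239752
ctrl1	non-LF	71	800	0.088750
# markers: CD161+CD69+
# U=1.0 p_one_tailed=0.5 method=exact n1=1 n2=1 direction=LF greater
```

The class-name map resolves six pixel classes —
`macrophage, myeloid, T cell, epithelium, ILC` plus an `unassigned`
stromal class — and the CD161⁺CD69⁺ double-positive fraction is ~2.7×
higher inside the follicle (0.240) than in the control region (0.089).
With a single region per group the Mann–Whitney comparison is
uninformative (p = 0.5); the 7-follicle-vs-5-control design used by the
quantification tests reaches p = 1/792 ≈ 0.00126 at complete separation.

Every artifact records the config hash and seed; rerunning an identical
config reproduces identical outputs, and commands refuse to combine
artifacts from different configs.

## Command line

`pixplore` exposes each stage: `simulate`, `preprocess`,
`hsne build|embed|drill`, `gate cluster|expand|assign`, `render`,
`quantify`, and `run` (full pipeline from a YAML config). `--help` on any
subcommand lists options.

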
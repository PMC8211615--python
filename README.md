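# nvcvis

Multimodal MRI fusion and 3-D visualization of neurovascular contact at the
brainstem.

The package implements a complete desk-scale pipeline for assessing
vessel–nerve contact from paired anatomical ("CISS-like": hyperintense CSF,
hypointense nerves/vessels/brainstem) and angiographic ("TOF-like":
hyperintense vessels) volumes:

1. **phantom** — synthetic paired CISS/TOF volumes with ground-truth masks,
   centerlines, a known rigid offset of the TOF grid, and the three artifact
   classes (flow-void signal loss, CSF pulsation speckle, near-brainstem
   contour fusion), so every downstream stage is testable without data.
2. **preprocess** — Perona–Malik anisotropic diffusion (flux-conservative,
   Neumann boundaries) and grey-value closing with a ball element.
3. **segmentation** — seeded volume growing with intensity windows, bounding
   boxes and barrier masks; four sub-volumes assembled with the fixed
   priority NERVE > CSF_VESSEL > BRAINSTEM > REST; nerve masks are imported
   as manual annotations (phantom truth stands in).
4. **registration** — closed-form landmark rigid fit, mutual-information
   refinement (Powell over a Gaussian resolution pyramid; Parzen-smoothed
   internal objective) and trilinear reformatting onto the fixed grid.
5. **fusion** — TOF vessels extracted by volume growing, inverted through a
   strictly decreasing linear ramp onto the hypointense CISS vessel range,
   transplanted voxel-by-voxel, and stamped with a dedicated VESSEL label.
6. **rendering** — orthographic front-to-back ray casting with per-label
   intensity→(color, opacity) look-up tables (implicit segmentation);
   vessels red, nerves yellow, brainstem light grey, rest transparent.
7. **scoring** — vessel–nerve contact detection (26-adjacency with a
   CSF-layer check) and the 0–5 vessel-quality ranking score
   operationalized via centerline display-window coverage.
8. **stats** — paired t-test (raw or summary-driven), Pearson chi-square,
   classic Levene; reproduces the reference before/after quality table from
   printed summaries.

## CLI

One subcommand per stage plus an end-to-end pipeline:

```sh
nvcvis phantom    --out run/ --seed 1 --size 96 [--touching]
nvcvis preprocess --in run/ciss.nii.gz --iters 5 --kappa auto --close-radius 3 --out pre.nii.gz
nvcvis segment    --in pre.nii.gz --csf-seed 40,20,48 --nerves run/mask_nerve.nii.gz --out labels.nii.gz
nvcvis register   --fixed run/ciss.nii.gz --moving run/tof.nii.gz --out T.json
nvcvis fuse       --ciss run/ciss.nii.gz --tof run/tof.nii.gz --transform T.json \
                  --labels labels.nii.gz --out fused.nii.gz --out-labels labels_fused.nii.gz
nvcvis render     --vol fused.nii.gz --labels labels_fused.nii.gz --view ap --out view.png
nvcvis score      --vol fused.nii.gz --centerlines run/truth.json --out scores.csv
nvcvis stats summary --out table.csv
nvcvis pipeline   --config config.json --out rundir/ --seed 1
```

The pipeline config is JSON; see `nvcvis.pipeline.DEFAULT_CONFIG` for the
schema and defaults.  Outputs (scores CSV, stats CSV, renders, log) are
reproducible from config + seed alone.

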
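# gjflux

Quantification toolkit for gap-junction trafficking assays, built around a
synthetic-data generator with exact ground truth so every analysis stage is
testable end-to-end without any external data.

## What it does

| Module | Purpose |
| --- | --- |
| `gjflux.simulate` | Generates every input the pipelines consume: confluent epithelial monolayer fields (nuclei, cell boundaries, compartment-assigned puncta, illumination bias, Poisson–Gaussian noise), 3D stacks of spherical plaques, log-normal cytometry event tables, linear enzyme-kinetics series, and voltage traces with a stimulation artifact plus an EPSP at a known latency. |
| `gjflux.image2d` | High-content 2D pipeline: plate illumination correction (200×200 median filter), nuclei segmentation with a 20–60 px diameter gate, seeded cell propagation, GFP transfection partitioning, puncta detection with an 8–20 px diameter gate, ITGA3 surface objects, three-way compartment assignment (surface / early endosome / lysosome, normalized to 100%), hierarchical site→well→condition aggregation, and bilateral-tract ROI densitometry (area, MGV, integrated density, area-weighted mean MGV). |
| `gjflux.volume3d` | 3D plaque detection (26-connectivity) with an inclusive 5–100 µm³ physical-volume gate and voxel-overlap interface colabeling. |
| `gjflux.cytometry` | Geometric-mean population summaries, transferrin-efflux normalization (per-condition t=0 saturation, then the reference condition at 7.5 min → 100%), surface/total receptor ratios with isotype background subtraction, and uptake normalization. |
| `gjflux.physiology` | Response latency from the stimulation-artifact onset to the EPSP onset (threshold crossing refined by rising-phase back-extrapolation), suprathreshold event frequency over a 5 s window, and OLS slopes of fluorogenic-substrate accumulation. |
| `gjflux.stats` | Type-II two-way ANOVA interaction, one-way ANOVA with Tukey–Kramer or Dunnett post hocs, Lilliefors-corrected KS normality check, group means ± SEM, significance stars, markdown reports. |

## CLI

All functionality is exposed through the `gjflux` command:

```bash
# synthetic data (OME-TIFF + ground-truth CSV)
gjflux simulate monolayer --config cfg.yaml --seed 1 --out plate/
gjflux simulate zstack   --seed 1 --out stacks/
gjflux simulate cytometry --n-events 10000 --out events.csv
gjflux simulate trace    --seed 1 --out trace.csv
gjflux simulate kinetics --slope 3 --intercept 5 --out series.csv

# quantification
gjflux quantify-2d --plate plate/ --out results/          # per-site/well/condition CSVs
gjflux quantify-3d --stack stacks/stack_seed1.tif --voxel 0.1,0.1,0.4
gjflux tracts --stack projection.tif --rois rois.csv
gjflux cytometry efflux --events events.csv --reference elevated
gjflux cytometry ratio --events tfr.csv
gjflux ephys latency --trace trace.csv --stim-times 5.0
gjflux ephys frequency --trace train.csv
gjflux kinetics slope --series series.csv
gjflux report --data tidy.csv --design age,genotype
```

Monolayer simulation configs are YAML mirrors of
`gjflux.simulate.MonolayerParams` (e.g. `field_shape: [576, 576]`,
`n_cells: 20`, `compartment_fractions: [0.6, 0.25, 0.15]`).

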
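# artroi — reverse transformation of generic ROIs for perfusion MRI

`artroi` implements and validates the *reverse transformation* (arT)
approach to automatic region-of-interest analysis of dynamic susceptibility
contrast (DSC) perfusion MRI. Instead of normalising measured parameter
maps into a template space — which resamples and thereby alters the
measured values — arT projects a single generic ROI template *backwards*
into each subject's native space through the inverse of the
spatial-normalisation deformation. Quantitative parameters (standardised
time-to-peak, cerebral blood volume) are then read directly off the
untouched native maps.

The package is aimed at perfusion-imaging methodologists who want to
(1) run the arT pipeline on their own NIfTI data (deformation fields and
tissue-probability maps from any normalisation tool), and (2) quantify how
much ROI-propagation error leaks into the perfusion parameters, using a
fully synthetic brain phantom with known ground truth.

## The statistics at its core

Spatial agreement of a native (reference) ROI and a transformed generic ROI:

- volume error — `VE = (V_nat − V_gen) / (0.5 (V_nat + V_gen))`, signed,
  bounded by ±2;
- Sørensen–Dice index — `SDI = 2|A ∩ B| / (|A| + |B|)`;
- surface-to-volume ratio — exposed voxel-face area over voxel volume
  (1/mm), a shape-compactness measure that predicts overlap robustness.

Functional agreement of ROI-mean parameter values (differences are
generic − native): bias with a normal-theory 95% CI, limits of agreement as
the 2.5th/97.5th percentiles of the differences, Pearson and Spearman
correlation, Lin's concordance coefficient
`CCC = 2 cov(x,y) / (σx² + σy² + (μx − μy)²)`, and the error of the linear
fit normalised by the reference mean,
`NRMSE = RMS(fit(i) − nat(i)) / mean(nat)`.

## Worked example

Run a small end-to-end study — synthetic cohort, perfusion maps, arT,
evaluation — and validate the report:

```sh
$ artroi study --n-subjects 36 --seed 1 --out study/
252 ROI pairs evaluated; pooled stdTTP bias -0.0394 s; report under study
$ artroi validate study/
[... all checks "passed": true ...]
```

`study/table_spatial.csv` then contains per-ROI medians ± MAD over the 36
subjects (seed 1):

| ROI | SVR [1/mm] | VE [%] | SDI |
|---|---|---|---|
| right basal ganglia | 0.65 ± 0.04 | −6.2 ± 5.0 | 0.862 ± 0.047 |
| pons | 0.59 ± 0.04 | −5.1 ± 7.2 | 0.892 ± 0.028 |
| right cerebellum | 0.45 ± 0.02 | −0.3 ± 4.9 | 0.915 ± 0.015 |
| right hemisphere | 0.21 ± 0.00 | 0.2 ± 1.4 | 0.956 ± 0.008 |

Small, high-SVR structures overlap worst; the cohort-level relationships
(`agreement.json`) quantify this: Spearman(SDI, log volume) = 0.65 and
Pearson(SDI, SVR) = −0.59. Pooled functional agreement over all 252 ROI
pairs: stdTTP bias −0.039 s with limits of agreement [−0.296, 0.072] s,
PCC 0.983, CCC 0.980, fit NRMSE 4.6%; CBV bias +11.5 a.u., PCC 0.984,
NRMSE 1.1%. In other words, even at realistic segmentation disagreement the
ROI-mean perfusion parameters transfer almost losslessly from manual to
generic ROIs — the point of the arT approach.

Other subcommands: `artroi phantom` (write a synthetic cohort as NIfTI),
`artroi perfmaps` (maps from a 4D DSC series), `artroi run` (arT for one
subject folder), `artroi evaluate` (compare two label maps), `artroi init`
(emit a config file with all defaults).

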
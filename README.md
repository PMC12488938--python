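# epiquant

Quantitative analysis of pluripotency-factor expression in the
post-implantation mouse epiblast.

Around gastrulation, the epiblast splits into a posterior NANOG-high /
SOX2-low domain that loses pluripotency early and an anterior SOX2-high
domain that retains it. Testing that picture quantitatively requires a chain
of analyses that this package implements end to end, for anyone working with
whole-mount confocal stacks, regional explant assays, or gastrulation-stage
single-cell expression:

- **Imaging** (`epiquant.imaging`) — depth-attenuation correction of
  multi-channel 3D stacks (`corrected = recorded / e^(−k·depth)`, per-channel
  `k` per micron), classical nuclear segmentation (Otsu +
  distance-transform watershed, 3D or per-slice, with a plug-in point for
  external label volumes), and per-nucleus features: volume, boundary
  measure, eccentricity, and average nuclear intensity (ANI) per channel.
- **Quantification** (`epiquant.quantify`) — positivity gating against an
  internally controlled negative region, flow-cytometry-style
  equal-probability density contours (5%/10% steps, outliers beyond the
  outermost contour), explant colony classing (≤2 foci excluded / 3–7 / >7),
  and the likelihood-ratio G-test.
- **Threshold scan** (`epiquant.thresholdscan`) — sweep a SOX2 ANI threshold
  τ, correlate each region's %cells-above-τ with its %GFP⁺ explant colonies,
  and report the signed-r² curve, its peak, and a randomised-region
  permutation null (mean ± SD per threshold, 21 iterations).
- **Gene screen** (`epiquant.genescreen`) — stage-wise Spearman correlation
  of every gene against *Nanog* and *Sox2*, blocked by mouse of origin
  (weights n_b − 1, within-block permutation p-values), Benjamini–Hochberg
  correction per stage × anchor, and the ≥2-timepoints co-regulation rule.
- **Information decomposition** (`epiquant.infodecomp`) — Bayesian-blocks
  discretisation (exact dynamic program over mid-point cell edges) and
  two-source Williams–Beer partial information decomposition: redundancy,
  unique terms, synergy, in bits, additive to machine precision.
- **Synthetic data** (`epiquant.synthdata`) — embryo stacks with
  anticorrelated NANOG/SOX2 gradients and depth attenuation, explant assays
  with a planted SOX2 threshold τ*, and expression matrices with planted
  correlated genes and mouse-level confounding — so every stage above is
  testable against known truth.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Simulate a ten-region explant assay whose colony outcome depends on the
fraction of cells above a planted SOX2 ANI threshold τ* = 46.6, then scan
thresholds against the colony percentages:

```sh
$ epiquant sim-assay --seed 3 --out assay
wrote 10 regions to assay (tau* = 46.6)

$ epiquant threshold-scan --features assay/ani_by_region.csv \
    --colonies assay/tallies.csv --grid-size 25 --iters 21 --seed 0 \
    --out scan.csv
best signed r2 = +0.977 at ANI 45.2 -> scan.csv
```

The scan recovered the planted threshold to within one grid step (45.2 vs
46.6 at a step of ≈ 4.5 ANI). In `scan.csv`, each row is one threshold with
the observed signed r² and the randomised-region null:

```text
 threshold       r2  null_mean  null_sd
 45.167933 0.977142  -0.014619 0.135282
 49.664359 0.960499  -0.009936 0.125201
 54.160784 0.889692  -0.010250 0.126363
 58.657210 0.797068  -0.011903 0.130000
```

The peak (+0.977) sits far above the null at that threshold
(−0.015 ± 0.135): the percentage of cells above ~45 ANI predicts colony
reactivation across regions, while shuffling regions destroys the
relationship. The same chain is available in Python via
`gen_explant_assay`, `scan_thresholds` and `randomized_null`.

Other entry points: `epiquant sim-embryo` / `quantify-stack` (stack →
per-nucleus feature CSV), `gate`, `colony-score`, `gene-screen`, `pid`.

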
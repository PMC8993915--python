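# crypsis

Integrative species-delimitation toolkit for cryptic taxa: discriminant
morphometrics, DNA-barcode mitotype diversity, averaged body-profile
imaging, and lightweight ensemble niche modelling with habitat-area
estimation.

## The problem

Cryptic species cannot be told apart by eye, yet they can be delimited by
combining independent evidence classes. The motivating case is a Nearctic
ant long confused with a widespread Palearctic look-alike: single workers
are separated by a linear diagnostic score on four measurements, nest
samples by an averaged mesosoma profile, populations by mitochondrial
barcode diversity, and the invasion risk of the introduced look-alike by
a niche model projected onto the new continent. `crypsis` packages each
of these stages as tested, reusable operations with seeded synthetic
generators so the whole pipeline runs with known ground truth.

## The quantitative core

- **Diagnostic score.** For measurements in mm and a raw setae count,

  D = −43.792·GuHL + 113.436·dClAn + 75.68·MP6 − 0.431·nSt − 10.075,

  with D < 0 diagnosing the Nearctic species. Fresh two-group LDA
  (closed-form S⁻¹(μ₁−μ₂) with a midpoint boundary), AIC-based stepwise
  logistic variable selection, Wilcoxon/Fisher group comparison and PCA
  support building such scores from new tables.
- **Barcode diversity.** Mitotype collapsing (strict or missing-tolerant
  wildcard policy), Nei's unbiased haplotype diversity
  h = n/(n−1)(1−Σp²), nucleotide diversity π as mean uncorrected
  p-distance with pairwise deletion, and alignment summaries
  (variable sites, missing fraction, GC).
- **Profile averaging.** Scale/position standardization to a canonical
  frame, black-and-white conversion, pixel-wise mean darkness.
- **Niche modelling.** Ridge-logistic reference learner (pluggable
  registry), bootstrap ensembles weighted by TSS, evaluation by AUC /
  max-TSS / kappa, cell-wise projection onto any raster stack with the
  training layers (including a second region), and habitat area above a
  probability threshold as qualifying-cell count × median spherical cell
  area (R = 6371 km).

## Worked example

```sh
crypsis simulate morpho --seed 2 --out sim
crypsis morpho --table sim/morpho.csv --out out
python -c "import json; r = json.load(open('out/morpho.json'));
print(r['D_nearctic'], r['D_palearctic'])"
```

which prints (seed 2):

```
{'max': 0.95, 'median': -2.97, 'min': -6.40} {'max': 7.99, 'median': 1.57, 'min': -1.48}
```

(values abbreviated to two decimals): on a synthetic two-group table
drawn from the published medians and ranges (39 + 49 specimens), the
diagnostic score's group medians fall on opposite sides of zero —
negative for the Nearctic group, positive for the Palearctic complex —
with a minority of individual specimens crossing the boundary. Across
seeds and at larger n the per-specimen sign accuracy settles around 90%.

Other stages run the same way:

```sh
crypsis simulate alignment --seed 1 --out sim   # 28 barcodes, 15 mitotypes
crypsis barcode --fasta sim/alignment.fasta --out out
crypsis simulate niche --seed 6 --out env
crypsis enm --grid env --points env/occurrences.csv --out out
```

`out/barcode.json` then reports k = 15 mitotypes, h = 0.899, π = 0.012
and a maximum uncorrected divergence of 5.9% for the diverse-species
design; `out/enm.json` reports ensemble AUC/TSS/kappa and habitat areas
(km²) above the 0.2 / 0.5 / 0.8 probability thresholds, which are
monotone by construction.

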
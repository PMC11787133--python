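# tlsquant

Spatial quantification of **tertiary lymphoid structures (TLSs)** in
endometrial cancer, downstream of any tumor/stroma/TLS segmentation.

Tertiary lymphoid structures are organized, B-cell-rich lymphocyte
aggregates that form in tumors under chronic immune stimulation.  Where a
TLS sits relative to the tumor invasive margin matters: structures hugging
the margin (**proximal TLSs, pTLSs**, < 500 µm) and structures farther out
in the peritumoral stroma (**distal TLSs, dTLSs**, 500–5000 µm) behave
differently — dTLSs share expanded B-cell clones with intratumoral
lymphocytes and track with better prognosis and immune-checkpoint-inhibitor
response.  `tlsquant` implements the analysis that turns per-case
segmentation label maps into those spatial calls and their downstream
statistics, for pathologists and computational biologists who already have
segmentation output (from a CNN, from polygon annotations, or simulated)
and need the quantification to be reproducible.

## What it computes

Given a class raster (`0 = background, 1 = tumor, 2 = stroma, 3 = TLS`)
with a microns-per-pixel resolution:

* **TLS extraction and classification** — 8-connected TLS components; area
  `A = n_px · mpp²`; centroid **c** = mean of member pixel centers; margin
  distance `d(c) = min over tumor pixels t of ‖c − t‖₂`; category
  *proximal* for `d < 500 µm`, *distal* for `500 ≤ d ≤ 5000 µm`, excluded
  beyond 5000 µm or when `A < 1000 µm²`.
* **iTIL score** — the map is tiled into 500 µm squares, each tile gets its
  plurality class, and the score is (# tumor tiles called TIL-positive) /
  (# tumor tiles).
* **Molecular subtype** — ordered cascade: POLE exonuclease-domain missense
  (residues 268–471) → MSI-H (≥ 2 frameshift indels in ≥ 4-copy tandem
  repeats) → CNV-H (altered fraction > 20% of assayed territory) → CNV-L.
* **Expression scores** — single-sample gene-set enrichment
  (rank-weighted ECDF difference, exponent α = 0.25), CYT
  (`√(GZMA·PRF1)`), and a user-weighted 18-gene GEP score; optional
  cohort-wide min–max scaling.
* **BCR clone overlap** — per TLS/TIL pair, shared CDR3 amino-acid clones
  among each sample's top-30 by read count; shared reads as a percentage of
  the TLS sample's total in-frame reads.
* **Survival and association** — Kaplan–Meier curves, multivariable Cox
  proportional hazards (Efron ties, Wald CIs; references: stage 1,
  age < 65, endometrioid, dTLS absent), 10-year administrative censoring,
  Mann–Whitney / Wilcoxon comparisons, Spearman correlations, cohort
  summary tables.
* **Synthetic data** — `tlsquant.simulate` generates every input with known
  ground truth: label maps with TLS disks planted at requested distances
  and areas, TIL calls at a chosen rate, variant/CNV profiles that classify
  to a requested subtype, expression matrices with planted signature
  effects, paired clonotype tables with a controlled shared-clone count,
  and survival cohorts with a chosen true hazard ratio.

## Worked example

```python
from tlsquant import summarize_case, classify_subtype
from tlsquant import simulate as sim

# a synthetic case: one TLS planted 250 µm from the tumor margin, one at 1200 µm
lmap, truth = sim.gen_labelmap([(250, 5000), (1200, 5000)], seed=3)
summary, records = summarize_case(lmap)
for r in records:
    print(f"TLS {r.component_id}: area {r.area_um2:.0f} µm², "
          f"distance {r.margin_distance_um:.1f} µm -> {r.category}")
print(summary.as_dict())

variants, segments = sim.gen_variant_profile("MSI-H", seed=5)
print(classify_subtype(variants, segments).as_dict())
```

prints

```
TLS 1: area 4944 µm², distance 249.7 µm -> proximal
TLS 2: area 5040 µm², distance 1200.0 µm -> distal
{'case_id': 'sim', 'n_ptls': 1, 'n_dtls': 1, 'tls_positive': True,
 'ptls_positive': True, 'dtls_positive': True, 'itil_score': None}
{'subtype': 'MSI-H', 'rule': 'frameshift_indels_in_repeats',
 'pole_position': None, 'msi_indel_count': 5, 'cna_fraction': 0.410523}
```

The planted 250 µm structure lands within half a pixel of its requested
distance and is called proximal; the 1200 µm structure is distal, so the
case is dTLS-positive — exactly the generator's truth record.  The variant
profile was built to be MSI-H: it has five frameshift indels in repeat
context (two suffice) and a 41% copy-number-altered fraction that the
cascade never reaches because the MSI rule fires first.

The package also ships a measured worked example
(`tlsquant.examples.repertoire_summary()`): twelve microdissected TLSs from
six cases with their margin distances and BCR read counts.  For instance
the first distal TLS of case 4 has 3,651 of 18,430 in-frame reads in clones
shared with the paired intratumoral sample:

```python
from tlsquant.repertoire import common_clone_percent
common_clone_percent(3651, 18430)   # 19.8
```

A command-line interface mirrors the library
(`tlsquant simulate|spatial|tilscore|subtype|scores|repertoire|survival|report`);
see `tlsquant --help`.

## Documentation

`docs/methods.md` describes the model and its assumptions, the coordinate
and boundary conventions, what the synthetic generators do and do not
emulate, and the package's numerical choices.
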
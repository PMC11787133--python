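# Methods

## Scope and model

`tlsquant` is the downstream half of an AI-assisted TLS analysis: it takes
per-case segmentation label maps (however produced — a CNN, polygon
annotations, or the bundled simulator) and quantifies the spatial
arrangement of tertiary lymphoid structures relative to the tumor invasive
margin, then carries the per-case calls through molecular subtyping,
expression scoring, B-cell-receptor clone overlap, and survival analysis.
Segmentation itself (model architecture, training, stain handling) is out
of scope; the package treats the label map as ground input.

## Coordinate and measurement conventions

* Grids are row-major, origin top-left, 0-based.  The physical position of
  pixel `(row, col)` is its **center**: `x = (col + 0.5)·mpp`,
  `y = (row + 0.5)·mpp`.  All areas and distances follow from this, so a
  `k×k` pixel block at resolution `mpp` has area exactly `k²·mpp²` µm².
* The **tumor invasive margin** is represented by the set of tumor-class
  pixel centers (union over all tumor components; no minimum tumor
  component size by default, configurable).  The margin distance of a point
  is its Euclidean distance to the nearest tumor pixel center.
* TLS components use 8-connectivity (configurable to 4).  A component's
  "center" is its area centroid — the mean of member pixel centers — which
  is deterministic and standard for blob geometry.
* Category boundaries: proximal `[0, 500)` µm, distal `[500, 5000]` µm
  (both ends of the assessment window included), excluded beyond; minimum
  retained area 1000 µm².  All four numbers live in `PipelineConfig`.
* Components touching or inside the tumor mask get distance 0 and are
  therefore proximal: an intratumoral structure is at the closest possible
  margin distance.
* Distances are Euclidean, not geodesic around tissue gaps.  This is an
  assumption; maps with large internal voids would need a geodesic variant.

## Numerical choices

* **Margin distance of arbitrary points** is computed by exact nearest-
  neighbor search over tumor pixel centers (a k-d tree).  The Euclidean
  distance transform is exact only at pixel centers, while TLS centroids
  fall between them; the k-d tree gives machine-precision agreement with
  the brute-force minimum at any query point.  A whole-map EDT-based
  distance field (`margin_distance_field`) is kept for visualization and
  binning; both routes are tested against an exhaustive-scan oracle.
* **Tiling** lays 500 µm squares from the origin; a partial edge tile is
  retained iff at least half a full tile's area lies on the map.  A tile's
  class is the plurality of its pixel classes with ties broken
  tumor > TLS > stroma > background — conservative toward the tumor
  denominator of the iTIL score.  With equal-area tiles the "area of
  TIL-positive tiles over total tumor area" reduces to a count ratio.
* **ssGSEA** ranks genes per sample (ties: average rank; walk order ties:
  gene identifier, for determinism), weights in-set steps by `rank^α` with
  α = 0.25 (the originating method's default), and sums the difference
  between the weighted in-set ECDF and the uniform out-of-set ECDF.  A set
  covering every matrix gene leaves the out-of-set ECDF undefined and is
  rejected.  At α = 0 the statistic is invariant under any strictly
  increasing per-sample transform.
* **Repeat context** for the MSI rule reads "more than three consecutive
  repeats" as ≥ 4 copies of a tandem unit, unit lengths 1–6 scanned; both
  knobs are configurable and recorded in output metadata.  The CNA-high
  threshold is strict (> 0.20), and the POLE domain bounds 268–471 are
  inclusive.  The CNA denominator is the explicit assayed territory in the
  configuration (default 1 Mb of panel backbone), never an implied whole
  genome.
* **Clone overlap** uses the CDR3 amino-acid sequence as the default clone
  key (a V/J-qualified key is available), counts shared reads on the TLS
  side, and divides by the TLS sample's *total* in-frame reads rather than
  its top-30 subtotal — the convention under which the bundled worked
  example's percentages (19.8, 39.9, 12.6, 5.5) reproduce exactly.
  Top-N ties are broken lexicographically by CDR3.
* **Survival**: administrative censoring at 10 years precedes modeling and
  is idempotent.  Cox models use the Efron tie correction and Wald
  intervals (lifelines backend, Newton tolerance tightened to ~1e-9 so the
  optimum matches a direct partial-likelihood Newton iteration to 1e-6).
  Categorical covariates expand against fixed references: stage 1,
  age < 65, endometrioid histology, dTLS absent.  No multiple-testing
  adjustment is applied; p-values are reported unadjusted.

## Synthetic generators: what they emulate, and what they do not

Every generator is deterministic given (seed, parameters) and self-checks
its truth against the corresponding analysis operation before returning.

* `gen_labelmap` plants circular TLSs around a central tumor (disk, or a
  harmonic-perturbed blob) with a stromal band filling the peritumoral
  zone.  Disk centers are placed along rays and corrected iteratively
  against the exact nearest-tumor-pixel distance, then re-centered on the
  rasterized centroid, giving centroid distances within one pixel diagonal
  and pixel areas within 5% of the request.  Default resolution is
  4 µm/px with a 400 µm tumor radius — coarse enough that a case with
  TLSs out to ~1.5 mm stays under a megapixel, fine enough that the 1000
  µm² area filter resolves.  What it does **not** emulate: H&E appearance,
  segmentation errors (a label-noise knob would sit here but defaults to
  none), irregular TLS shapes, or multi-focal tumors.
* `gen_til_calls` flags every non-background tile i.i.d. Bernoulli(p), so
  the expected iTIL score equals p and the binomial standard error governs
  calibration tests.
* `gen_variant_profile` inverts the subtype cascade: requested-subtype
  profiles include the rule's evidence plus, randomly, evidence for
  lower-priority rules (a POLE profile may also satisfy MSI and CNV-H
  criteria — the cascade order must still resolve it).  Homopolymer
  contexts are embedded in verified non-repetitive flanks.
* `gen_expression` draws log-normal values with the signature genes'
  log-mean shifted by the effect size (in log-SD units) in dTLS-positive
  samples; background genes are exchangeable.  Real co-expression
  structure, library-size effects and batch effects are not modeled, so
  passing tests demonstrate the scoring arithmetic, not robustness to real
  RNA-seq noise.
* `gen_clone_tables` gives both samples Zipf-distributed read counts
  (exponent 1.5 — heavy-tailed like real clone-size distributions; the
  exact law is irrelevant to the overlap statistics) with a controlled
  number of shared CDR3s, placed at the top ranks by default or shuffled.
* `gen_survival_cohort` uses exponential event times with rate
  `λ·HR^dTLS`, so the Cox estimand equals the generative hazard ratio.
  Uniform censoring `U(0, b)` has `b` solved numerically so the expected
  pre-administrative censoring fraction hits the target; administrative
  censoring at the 10-year horizon follows.  Defaults mirror the pooled
  study conditions: n = 559, dTLS prevalence 0.45, baseline rate
  0.04/year (≈ one-third cumulative mortality at 10 years), censoring
  fraction 0.3, and the recovery suite targets the reported multivariable
  dTLS hazard ratio of 0.56.  Covariate marginals (stage ≈ 64/9/22/5%,
  endometrioid ≈ 76%, age ≈ N(63, 10)) mirror a large endometrial-cancer
  cohort's margins only; joint structure is not claimed.

## Worked-example data

`tlsquant.examples` bundles a measured six-case microdissection series
(twelve TLSs with margin distances, total in-frame BCR reads, shared-clone
reads and unique shared clones) and per-cohort stage/histology counts used
by the summary-table checks.  One total read count (case 3, TLS 2) is not
recoverable from the source material and is stored as missing; no statistic
is derived from it.  The bundled signature GMT (12-chemokine, CXCL13,
plasma cell, Tfh, Th1, Th1/B, TLS imprint, CYT) is an editable
reconstruction of commonly cited signature lists and is configuration, not
ground truth.  The 18-gene GEP weights are deliberately **not** shipped:
they must be user-supplied, and `gep_score` errors on missing genes under
the strict policy.

## Known limitations

* One label map per case; multi-slide cases must be merged upstream (or
  analyzed per slide and aggregated by maximum).
* The margin is purely class-geometric: no smoothing of the tumor boundary,
  no exclusion of artifactual single-pixel tumor islands unless a minimum
  tumor-component area is configured.
* ssGSEA significance (permutation testing) is out of scope; scores are
  descriptive and compared between groups with rank tests.
* The acceptance simulations run at desk scale (hundreds of cases,
  hundreds of replicates); they validate estimator behavior under the
  stated generative conditions, not on any real cohort.
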
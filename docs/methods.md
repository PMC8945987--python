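# Methods

## SILAC filtering and regulation calling

Input is one protein per row with a linear treatment/control abundance
ratio, a p-value, a peptide count, and a search-engine confidence tier.
Three filters are applied jointly, all boundaries inclusive:

* confidence must be "high" (the Proteome Discoverer low-FDR tier);
* peptide count ≥ 2 ("more than one peptide");
* p ≤ 0.05;
* |fold change| two-fold on the linear scale: ratio ≥ 2 **or** ≤ 0.5.

The inclusive conventions (ratio exactly 2, p exactly 0.05 pass) are
deliberate and configurable via `FilterCriteria`; the two-sided fold
rule is symmetric under ratio inversion, and `call_regulation` inherits
it: `call(r) = up ⇔ call(1/r) = down`.  Rows whose ratio or p-value
fail to parse are dropped at read time and tallied in a QC log — a
missing value never counts as passing.  Summary percentages for the
up/down pie are computed over regulated (up+down) proteins only.

## KFERQ-like motif rules

Residue classes: hydrophobic {F,I,L,V}, basic {K,R}, acidic {D,E},
phospho-mimic {S,T,Y}, anchor {Q}, acetyl-mimic anchor {K}.  A
pentapeptide is **canonical** when Q sits at position 0 or 4 and the
four flanking residues contain 1–2 hydrophobic, 1–2 basic and exactly
one acidic residue (all four must be classed; a flanking Q or any other
unclassed residue disqualifies the window, so N is *not* accepted as a
Q substitute).  **Phospho-activated**: not canonical, but exactly one
flanking S/T/Y counted as acidic completes the composition (two S/T/Y
can never work — the second would stay unclassed).  **Acetyl-
activated**: a terminal K treated as the Q anchor completes the
composition.  **Phospho+acetyl**: both relaxations at once.  Priority
is total — canonical > phospho > acetyl > phospho+acetyl > none — so no
window carries two classes; the C-terminal anchor is tested first, so
KFERQ itself reports a C anchor.

Two independent routes compute these rules: the scalar classifier
(composition counting with relaxation flags) and a vectorized census
over all 20⁵ = 3,200,000 windows.  The canonical tally has a
combinatorial closed form, 2·[C(4,2)·4²·(2·2·2) + C(4,2)·2²·(2·4·2)] =
2304, and the test suite additionally checks the classifier against a
brute-force substitution oracle (replace one S/T/Y by D, or a terminal
K by Q, and re-test the canonical rule literally).

Per-protein categories for reporting are exclusive: {canonical},
{phospho}, {acetyl}, {phospho,acetyl}, {canonical,phospho},
{canonical,acetyl}, all three, or no motif.  The dual phospho+acetyl
hit class is folded into both parent classes by default (a protein
whose only motif needs both modifications counts toward phospho and
acetyl potential); `fold_dual_into_parents=False` surfaces it
separately.  Breakdown panels report (i) % of proteins with ≥ 1 motif,
(ii) % up/down among motif-containing proteins, (iii) % per category
over motif-containing proteins; panels whose denominator is empty are
`None`, never 0.

## Puncta quantification

The pipeline mirrors ImageJ-style particle analysis on two-channel
fields:

1. **Normalization**: each channel is min-max rescaled to [0,1] (the
   Phansalkar formula's domain); a constant channel maps to zeros.
2. **Nucleus seeds**: global Otsu on the DAPI channel, connected
   components, area ≥ 30 px.  Overlapping nuclei merge into one seed —
   a known limitation, covered by a test.
3. **Cell territory**: the reporter channel is smoothed (Gaussian,
   σ = 2 px) and thresholded with the *lower* split of a 3-class
   multi-Otsu — the channel genuinely holds three intensity populations
   (background, cytoplasm, puncta), and a 2-class Otsu can latch onto
   the bright puncta and discard the cell body.  A seeded watershed on
   the Sobel gradient of the smoothed channel, restricted to that
   foreground, yields one basin per nucleus; a seed outside the
   foreground produces an empty region plus a warning.
4. **Local threshold**: Phansalkar's
   `t = m·(1 + p·e^(−q·m) + k·(s/r − 1))` with the ImageJ Auto Local
   Threshold defaults k = 0.25, r = 0.5, p = 2, q = 10, radius 15 px,
   circular neighborhood, mirror padding, strict `>` comparison.  On a
   constant bright patch s = 0 pulls t below m, so everything is
   foreground — a property of the formula that the tests assert as
   such.  The `e^(−q·m)` term is what suppresses dim cytoplasm: it
   raises t well above the local mean wherever m ≲ 0.2.
5. **Matched filtering**: before thresholding, the reporter channel is
   low-pass filtered with σ_pre = 4/3·σ_spot (default spot width
   σ_spot = 1.5 px).  At the snr-5 detection limit a pixel-level
   threshold cannot separate spot peaks from cytoplasm noise — the
   noise margin is only ~2.5 SD — while smoothing at slightly above the
   matched width buys a ≳3.4 SD margin at modest cost in peak height.
6. **Particles**: 8-connected components; components holding several
   local intensity maxima (min distance 3 px) are split between them by
   a marker watershed, the ImageJ-style separation of touching spots.
   The area gate defaults to the area of a 1·σ_eff disk (minimum) and a
   4·σ_eff disk (maximum), σ_eff² = σ_spot² + σ_pre² — a genuine
   punctum must at least cover its own core.  Explicit
   `min_area`/`max_area` values override the derivation.
7. **Prominence gate**: min-max normalization stretches pure noise to
   full scale on fields with no real puncta, so every candidate must
   peak ≥ 7.5 robust SDs (noise estimated as 1.4826·MAD of the
   intracellular high-frequency residual, propagated through the
   pre-filter) above the median of its own surrounding ring.  The ring
   excludes only the particle's own pixels: a piece split out of a
   large noise blob measures against its siblings and fails, while an
   isolated punctum measures its full height.  Noise-excursion maxima
   on fields of this size reach ~6 SDs; spots at the snr-5 design limit
   measure ~9–13, so 7.5 separates the two regimes with margin on both
   sides.
8. **Assignment**: each particle goes to the cell label under its
   (unweighted) centroid; centroids on background are discarded and
   tallied, so per-cell counts plus discards equal the particle count
   exactly.
9. **Group comparison**: a two-sided unpaired t-test (equal variances,
   Welch optional) on per-replicate *mean* counts — the replication
   unit is the experiment, not the cell, mirroring an n = 4 design.
   Two degenerate identical groups return p = 1 explicitly.

## Synthetic data

`gen_quant_table` plants "up" effects uniform on [1, 2.5] log2 units,
"down" on [−2.5, −1], nulls at 0, and draws k = 3 replicate log2-ratios
with SD 0.2 by default (a triplicate design); the reported ratio is
2^mean and the p-value a one-sample t-test of the replicates, so ratio
and p are jointly realistic.  Peptide counts are 1 + Poisson(4) and the
confidence tier is "high" with probability 0.9 — the quality filters
therefore remove some planted-regulated proteins *by design*, and
truth-recovery comparisons are made over the quantifiable subset
(high-confidence, ≥ 2 peptides).  In the noise-free limit the sample SD
of identical replicates collapses and p is set to 0 (non-null) or 1
(null) explicitly.

`gen_motif_proteins` draws backgrounds from {A,G,M,P,W,C} only — no
residue of any motif class, so no accidental motif can form — and
inserts one pentapeptide of the requested class built from the class
recipe.  Every emitted sequence is re-scanned and resampled until
observed hits equal planted hits exactly (self-validation).  With
`protein_ids` given, classes are assigned round-robin to an existing
table's proteins, which links the proteomics and motif stages.

`gen_cell_image` renders 512×512 two-channel fields (a desk-scale
stand-in for 2048×2048 acquisitions): nucleus disks (radius 9 px,
intensity 0.8) on channel 0; cell disks (radius 26 px) with cytoplasm
baseline 0.08, Gaussian puncta of width σ = 1.5 px and amplitude
snr × noise_sd, and additive Gaussian noise (SD 0.08) on channel 1,
clipped to [0,1].  SNR is defined as spot amplitude / noise SD.  Cells
are placed without overlap (bounded rejection sampling; failure
raises); cell masks are disjoint by construction; puncta sit in the
cytoplasm (outside the nucleus disk) with mutual separation ≥ 4σ.
Poisson noise is available but off by default.  Everything is
bit-identical under a fixed seed.

What the generator does **not** emulate: photoactivation/bleaching
kinetics, 3-D structure, non-disk cell shapes, uneven illumination,
and spatially correlated (non-white) background — so passing tests
demonstrate the correctness of the algorithmic chain under controlled
conditions, not robustness to every real-microscopy artifact.

## Relative-quantification utilities

`ddct` implements 2^−ΔΔCt (ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt relative to a calibrator); swapping sample and calibrator inverts
the fold.  `normalized_ratio` implements loading-control-normalized
band ratios, invariant under common intensity scaling.  Both are
property-tested over randomized inputs.

## Reproducibility

A single YAML/JSON config drives `run_pipeline`; seeds are explicit for
every stochastic stage and a rerun with the same config is byte-
identical (hash-checked in the tests).  The run log echoes version,
seeds, parameters, and per-stage in/out counts so the filter cascade is
auditable.  `scripts/acceptance.py` re-derives the headline quantities
from scratch at the following problem sizes: the full 3.2 M-window
census; 1000-protein tables for filter recovery; 100 cells (10 fields)
at snr 5 for detection precision/recall; 8-cell fields for the
monotone response over {0, 2, 4, 8, 16} planted puncta per cell and
for the 8-vs-4, n = 4 treatment comparison.

## Known limitations

* The motif rule set is the classical composition rule; the web tool
  used in the original analyses does not publish its exact rules, so
  counts on real proteomes may differ in detail.
* Touching nuclei merge into one seed; heavily overlapping cells are
  split by watershed but counted against one seed each.
* Particle splitting relies on distinct local maxima; puncta closer
  than ~3 px after smoothing can still merge (the main recall cost at
  high densities).
* Percentages in breakdown panels are integer-rounded, so panels sum
  to 100 ± 1.
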
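# Methods

## The model

A wheat line carrying barley introgressions is represented on a concatenated
wheat+barley ("in silico hybrid") reference as a per-bin copy-number function
over a 1-Mb grid: euploid wheat bins are disomic (copy number 2), barley bins
default to 0, and structural events rewrite the function. The observable is
the per-bin read count of a low-pass GBS library mapped against the hybrid
reference; its normalized value separates presence (≈ 1) from absence
(≈ cross-mapping background), and maximal runs of like bins are the
structural blocks of the line.

### Reference geometry

Chromosomes are pure coordinate objects (name, subgenome, length and
centromere position in Mb, homoeologous group); no sequence is handled. The
default table holds the 21 bread-wheat and 7 barley chromosomes at the scale
of the public CS and Morex assemblies (18,489 bins at 1 Mb). The coordinates
every packaged structural call depends on are pinned by block lengths that
sum exactly: 6B = 345 + 386 = 731 Mb; 6H = 217 + 36 + 28 + 279 = 560 Mb with
the centromere placed at 253 Mb (the boundary between the two small interior
blocks — an assumption, since the exact 6H centromere coordinate is not
fixed by the data the scenarios encode); 4B = 673 Mb with the last 356 Mb
forming 4BL; 4H = 647 Mb with the last 335 Mb forming 4HL; 3B = 851 Mb.
The remaining lengths and centromeres are rounded assembly-scale defaults
and no reported quantity depends on them. 6H is also quoted as 561 Mb in
some sources; 560 (the block sum) is used throughout, and the percentage
summaries are insensitive to the difference.

Bins are half-open `[i, i+1)` Mb intervals; a trailing partial bin is kept
and its counts are rescaled by its length fraction during normalization.
Internal coordinates are 0-based half-open Mb; printed labels are 1-based
inclusive (`[217, 253) → "218–253"`). Published label conventions for such
blocks are not perfectly self-consistent at the ±1 level, so block *lengths*,
not label strings, are the quantities this package treats as exact.

### Structural events and the pericentric inversion

Karyotypes are built by applying events in order: `arm_replacement` (the
compensating centric fusion: one wheat arm zeroed, the homoeologous barley
arm set to 2), `terminal_loss` / `interstitial_deletion` (bins to 0),
`whole_addition` / `whole_loss`, and `pericentric_inversion`. The inversion
is implemented as a genuine interval reversal: the positional order of
reference bins inside `[p, r)` is reversed and the centromere point maps to
`p + r − c`. Copy number is indexed by reference bins throughout, so an
inversion alone changes nothing observable on a whole chromosome — but a
subsequent arm replacement computes arm membership on the *rearranged*
chromosome, which is exactly how one fusion carrier ends up holding
`[0,217) ∪ [253,281)` of 6H and the complementary carrier `[217,253) ∪
[281,560)`.

### Count model

Per-bin counts are drawn as `Poisson(λ_b · m_b · len_b)` with
`λ_b = depth · cn_b/2 + cross · depth`, where

- `depth_per_bin` (default 30) is the expected count of a full-length
  disomic bin — low-pass territory where Poisson noise dominates;
- `m_b` is a unit-mean gamma mappability factor with variance
  `mappability_dispersion` (default 0.005, i.e. ±7% bin-to-bin rate
  variation), giving the negative-binomial-like overdispersion real
  restriction-site landscapes produce without modelling the sites;
- `cross` is the cross-mapping leak onto absent bins: 0.011 of depth onto
  barley bins, 0.004 onto wheat bins — midpoints of the observed background
  ranges (0.009–0.013 and 0.002–0.006) for parental lines on the opposite
  subgenome. A flat rate is assumed; real cross-mapping probably
  concentrates in conserved regions, which this generator does not emulate.

With these defaults present-bin normalized coverage concentrates around
0.85–1.20, matching the observed parental present-bin band, and absent-bin
coverage sits near 0.01. A single seeded stream is consumed in reference
order (bit-identical reruns; no partial re-simulation — simplicity over
resumability). `simulate_read_positions` draws positions from a second
stream derived from the same seed, so counting the emitted placements
reproduces the count table exactly while leaving it unchanged.

What the simulator does *not* emulate: restriction-site clustering, GC and
mappability structure beyond the flat gamma factor, alignment error beyond
the flat leak, and heterozygous (monosomic) lines — monosomic bins simulate
at half depth and the default present threshold (0.4) classifies them
present, which is the desired reading for a monosomic carrier but means the
pipeline does not *distinguish* disomic from monosomic dosage. Passing tests
therefore demonstrate correctness of the analysis on an idealized coverage
process, not robustness to every artefact of real GBS libraries.

## Normalization

The published protocol this analysis follows does not restate its
normalization formula, so the estimator here is the package's own choice:
`normalized_b = raw_b / (M · len_b)` with `M` the **median of non-empty bin
counts**. The median is robust to the large absent fraction a translocation
line produces (a third of the barley subgenome present, arms missing) and
centres present disomic bins at 1.0. A `mean_top_half` alternative is
exposed behind a flag. Consequences: genuinely observed normalized values
from real libraries (e.g. per-region means like 1.079) are reproducible only
up to the unknown original estimator and are treated as calibration targets,
never asserted.

## Segmentation

Two thresholds with a gap: absent ≤ 0.15 < intermediate < 0.4 ≤ present.
The defaults sit between the largest observed absent-region value (0.233)
and the smallest observed present value (0.516), roughly in log-space
balance with the simulated distributions. Intermediate bins take the state
of the nearer resolved bin on the chromosome; at equal distance the flank
whose run mean is closer in value wins (left on a residual tie); an
intermediate run touching a chromosome end takes its single flank; an
all-intermediate chromosome falls back to the threshold midpoint.

Smoothing flips the shortest (then leftmost) interior run under `min_run = 3`
bins whose flanks agree, iterating to a fixpoint; terminal runs are never
flipped so real terminal blocks survive. Three bins suppresses isolated
dropouts while preserving the smallest real block the scenarios contain
(28 Mb). The smoothed states are merged into maximal `SegmentCall`s that
tile each chromosome. This is a deterministic, auditable threshold
segmenter, adequate at GBS signal-to-noise where present and absent means
differ by two orders of magnitude; an HMM would add latitude at much lower
depth but is deliberately not implemented.

## Event calling

- **Arm status**: fraction of each arm's length inside present segments;
  ≥ 0.9 present, ≤ 0.1 absent, else partial.
- **Centric fusions**: called when one wheat arm is absent, its partner
  present, and the same-group barley chromosome shows the complementary
  pattern. The barley side uses a relaxed 0.75 presence bound because a
  pericentric inversion can shift ~36 Mb across the centromere (the 6HS
  carrier holds only 217/253 ≈ 0.86 of its nominal arm) while the line is
  still named by arm. Names put the short arm first (`T4BS.4HL`). Both
  wheat arms absent is reported as a whole loss, never a fusion.
- **Deletions**: absent segments ≥ 5 Mb (below that, smoothing artefacts
  dominate) on majority-present wheat chromosomes; terminal if they touch an
  end. The pipeline masks absent segments that coincide (≥ 80% overlap)
  with an arm lost to a called fusion, so lost arms are not double-reported.
- **Pericentric inversion**: requires two carriers whose present-sets are
  near-disjoint (≤ 5% overlap) and near-complete (≥ 95% union), each with at
  most two present runs, interlocking as `[0,p)∪[q,r)` vs `[p,q)∪[r,L)`
  (boundaries matched to ±1 bin). One run each is a clean fission — no call;
  more fragmented patterns produce a diagnostic instead of a call. The
  conservatism is deliberate: the inference is indirect, and the origin of
  the inversion (parental genome vs translocation-specific vs reference
  mis-scaffolding near the centromere) is outside what coverage can decide,
  so the package reports the geometric call only.
- **Carrier frequency**: percent of screened plants carrying an event, one
  decimal.

## Problem sizes and determinism

Simulated analyses run at full scale: 18,489 one-Mb bins across 28
chromosomes, depth 30 per present bin (~4×10⁵ reads per line), which a
single CPU processes in well under a second per line. All randomness flows
from one integer seed per run; identical configuration and seed reproduce
byte-identical reports (timestamps are excluded from reports by design).
The boundary-recovery property (≥ 95% of true block boundaries within ±1
bin) is evaluated over 20 seeds of the T6HS.6BL scenario.

## Known limitations

- 1-Mb resolution: no sub-bin breakpoint refinement, matching the bin size
  of the analysis it implements.
- The centromere of 6H at 253 Mb is a modelling choice (see above); arm
  fractions on 6H shift slightly if it is moved, which is why the fusion
  caller's barley-side bound is relaxed.
- No duplicate marking, paired-end logic, or per-base depth; SAM input is
  filtered only by mapped flag and MAPQ ≥ 20 (an explicit default — the
  upstream protocol's quality filters are not specified).
- The dichotomous present/absent model cannot report dosage (disomic vs
  monosomic); extending the classifier with a half-dosage band would be the
  natural next step.
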
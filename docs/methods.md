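# Methods

## The assay and what the software models

Glycan-seq profiles cell-surface glycans with a panel of lectins, each
conjugated to a unique DNA barcode through a photocleavable linker. Lectins
bind the glycans on intact cells; UV exposure releases the bound barcodes,
which are amplified and sequenced. The number of reads carrying a lectin's
barcode is therefore a proxy for how much of that lectin bound, and the
vector of per-lectin fractions is the sample's glycan profile. This package
implements everything downstream of the sequencer: barcode extraction and
counting, normalization, clustering, and differential analysis between two
sample groups, plus a simulator that generates sequencer-like input with
known ground truth.

## Read matching

Reads are short (26 bp on a MiSeq in the motivating design). The first
`prefix_trim` bases (default 3) are uninformative and removed. The next
`barcode_length` bases are compared position-by-position against every panel
barcode, with mismatches counted separately in two region classes:

- *flanking* regions (default spans `[0,7)` and `[15,22)` of a 22-base
  barcode), budget `max_flank_mismatches = 2` — a **total** over both
  flanks, the stricter reading of a per-"flanking-region" budget;
- the *middle* region (default `[7,15)`), budget `max_middle_mismatches = 1`.

A barcode within both budgets is a candidate. One candidate → assigned;
several → assigned to the unique candidate with the smallest total mismatch
count, with ties declared `ambiguous` and excluded from counts (deterministic
and conservative; the tally is reported in QC output); none → `unassigned`;
reads shorter than prefix + barcode → `too_short`. `N` counts as a mismatch
wherever it appears, so low-quality reads fall out through the budgets
rather than through a separate filter. Quality scores are not consulted and
indels are not modeled — the rule is positional (Hamming-style) by design.

The barcode coordinates themselves are configurable in the panel file
(`#layout:` header); the defaults above are the package's own choice of a
22-base barcode that fits a 26 bp read after the 3-base trim. Both mate
files of a paired run are accepted, but only read 1 is matched: the stated
rule operates on the single barcode-bearing read, and the simulator's mate-2
files are filler.

### Separability

A read can satisfy both budgets for two different barcodes iff in every
region the inter-barcode mismatch count is at most twice the region's
allowance (construct the midpoint sequence: put half the differing positions
on each side — always possible over a 4-letter alphabet).
`validate_separability` evaluates this exactly for every pair. The barcode
generator enforces a minimum pairwise Hamming distance of 7 by default,
strictly above the collision bound 2·2 + 2·1 = 6, so generated panels are
collision-free by construction and this is re-checked after generation.

## Normalization and positivity

A sample's profile entry is `100 · count_l / n_assigned`; ambiguous and
unassigned reads never enter the denominator. Rows sum to 100 by
construction (enforced to 1e-6), and the profile is invariant to the
sample's sequencing depth. A lectin is flagged *positive* in a group when
its group-mean percentage strictly exceeds a threshold (default 15), the
screening rule for choosing lectins to validate orthogonally; the strict
inequality follows the ">15" phrasing of that rule.

## Clustering

Sample rows are clustered agglomeratively (scipy) on their percentage
profiles; default Euclidean distance and average linkage, both configurable,
as the underlying study does not state its choices. No transform is applied
by default (the pipeline exposes the profile as-is); the acceptance-level
claim — two study groups split into two clusters at k = 2 — is robust to
the metric/linkage choice at the simulated effect sizes. Dendrograms are
exported as Newick with merge-height branch lengths, alongside the
leaf-ordered matrix for heatmaps.

## Differential analysis

Profiles are compositional: one lectin rising forces the others down, so
percentages are not tested directly. Following the ANCOM approach adapted to
lectin panels, for each ordered lectin *i* and every partner *j ≠ i* the
per-sample statistic is `log((x_i + c)/(x_j + c))` with pseudocount
`c = 0.5` on the percentage scale guarding zeros. Each partner log-ratio is
compared between the two groups with a two-sided Welch *t*-test; the
*(m−1)* partner p-values are Holm–Bonferroni adjusted **within lectin i's
family** (the natural reading of per-feature families; a whole-matrix scope
would be a different, stricter procedure), `W_i` counts adjusted rejections
at α, and `summary_p_i` is the minimal adjusted partner p. Significance
requires both `W_i ≥ ⌈0.7·(m−1)⌉` (the common W-fraction cutoff in ANCOM
practice) and `summary_p_i < α = 0.05`.

Choices left open by the adapted procedure, and how they are set here:

| knob | default | rationale |
| --- | --- | --- |
| per-pair test | Welch t | n = 3 per group is too small for a two-sided rank test to reach p < 0.05; Mann–Whitney is available for larger n |
| pseudocount c | 0.5 % | half a "count" on the percentage scale; only matters near zero |
| W cutoff | 0.7·(m−1) | standard ANCOM operating point |
| per-lectin p | min adjusted partner p | conservative single-number summary |

All four are exposed in `DifferentialConfig` and on the CLI so alternative
readings can be reproduced. Degenerate partner pairs (zero variance in both
groups) get p = 1 when the group means agree — exactly equal profiles yield
no calls — and p = 0 when they differ without noise.

The Holm step-down itself is the vectorized formula
`p̃_(i) = max_{j≤i} min(1, (m−j+1) p_(j))`, implemented directly; an
independent library implementation serves as a property-test cross-check.
With a planted single-lectin effect the expected behaviour is structural:
the effect lectin's ratios shift against all non-effect partners
(W ≈ m−1−k for k planted lectins), while a background lectin shifts only
against the k planted partners (W ≈ k), far below the 0.7 cutoff — which is
why recovery is exact at the simulated effect sizes.

## The simulator

What it emulates, per sample of the default conditions (two groups, pups vs
adult, n = 3; 39 lectins; depth 10⁵ reads):

- lectin counts drawn multinomially from the group composition over
  `(1 − contaminant_fraction)·depth` reads (uniform baseline; the planted
  effect multiplies chosen lectins by `fold_change` in one group and
  renormalizes — default 8-fold on SSA, TJAI, SNA, rABA in pups, the
  qualitative direction of the motivating comparison);
- a 3-base uniform-random prefix (the real prefix's nature — adapter
  residue or UMI — is unknown and never interpreted);
- i.i.d. per-base substitution errors at `error_rate` (default 0.005,
  a realistic MiSeq short-read substitution rate); no indels, matching the
  positional matcher;
- `contaminant_fraction` (default 0.05) uniform-random reads standing in
  for free barcodes and off-target material; the real background level is
  unknown, so this knob is a scenario parameter, not a calibration;
- optional Dirichlet overdispersion (`overdispersion > 0`) for
  between-replicate compositional variability; off by default so the default
  conditions are pure multinomial.

Every read's true label is recorded, truth tables and sample sheets are
written next to the FASTQ files, and identical seeds give byte-identical
outputs (a single `numpy` Generator drives sampling in a fixed order).

What it does **not** emulate — and what passing tests therefore do not show
about real data: PCR amplification bias, UV-release and binding-efficiency
variation between lectins, lectin cross-reactivity (reads are generated from
the true lectin only), index-hopping between samples, indels, and
quality-score structure. Real panels may also be less separable than
generated ones; the separability report exists precisely to check that.

## Numerical and reproducibility choices

- Matching is vectorized over read chunks (20k reads) against the whole
  panel; memory is independent of file size.
- Tie-breaks: ambiguous reads are dropped (reported in QC); report rows with
  equal (significance, W, summary_p) sort lexicographically by lectin name;
  stable sorts throughout.
- The run manifest contains version, parameters, input checksums and
  relative output paths, and deliberately no wall-clock timestamps, so a
  rerun with identical inputs is byte-identical and the manifest alone
  suffices to re-invoke the run; timestamps appear in the stderr log.
- Problem sizes used by the test suite: oracle equivalence on ~1.2·10⁴
  reads over 4 random panels; zero-noise identity at 6 × 10⁵ reads; the
  null study at 500 Monte-Carlo replicates of the count-level model
  (multinomial → profile → test), which isolates the statistical property
  from the read-level path that the exact-identity tests already pin down.

## Known limitations

- Two-group designs only; no covariates, no paired structure.
- The positivity threshold and the differential defaults are operating
  points, not fitted quantities; changing them changes calls.
- The separability check is exact for the budget rule given here but does
  not model sequencing-error correlation structure.
- Newick export encodes the dendrogram only (no support values).
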
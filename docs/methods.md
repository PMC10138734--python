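# Methods

## Haploblock model

A haploblock is operationalised as a maximal run of adjacent fixed-width
reference bins whose alignment-identity medians indicate shared ancestry.
The model's assumptions, made explicit:

- **One observation per alignment.**  Each local alignment contributes its
  percent identity once, to the bin containing its reference midpoint.
  Alignments are not split across bins and medians are unweighted by length:
  every alignment is a single observation of local divergence.  Midpoint
  assignment keeps the estimator simple and makes the bin histogram an exact
  function of midpoints (which the tests exploit).
- **Absence of alignment is absence of evidence.**  A bin with no alignments
  terminates any run and can never join a block: a haploblock claims
  *continuous* shared sequence, and an unaligned 5-Mb window cannot support
  that claim.
- **Finite-precision median equality.**  Floating-point medians are almost
  never bitwise equal, so "identical median" is evaluated after half-up
  rounding to `median_rounding` decimals (default 2).  The rounding quantum
  is therefore the resolution at which two bins can be called "the same
  haplotype"; coarser rounding merges more aggressively.
- **Two merge modes.**  `identical_median` (the default) merges bins sharing
  one rounded median; `threshold` merges any adjacent bins that all clear the
  identity cutoff, then takes the median of bin medians as the block value.
  The two are not equivalent — identical-median fragments a tract whose bin
  medians wobble across a rounding boundary, threshold mode bridges distinct
  but uniformly high medians — and which better matches a given study design
  depends on whether "same haplotype" or "similar enough" is meant.  Both
  are first-class and tested.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `bin_size` | 5,000,000 | bp | width of the fixed reference bin grid |
| `min_aln_len` | 20,000 | bp | minimum reference span of a usable alignment |
| `identity_cutoff` | 95 (99 for very close pairs) | % | block-level similarity cutoff |
| `merge_mode` | `identical_median` | — | run-formation rule (see above) |
| `median_rounding` | 2 | decimals | precision of median comparison |
| `min_bins` | 1 | bins | minimum run length reported |
| `strict_cutoff` | true | — | cutoff comparison is `>` (matching ">95%" conventions) |

Two minimum-alignment-length conventions circulate for this analysis (20 kb
and 10 kb); 20 kb is the default here and the alternative is one parameter
away.  MAPQ-based filtering (`min_mapq`, e.g. 60 with a 750-bp length floor)
applies to PAF input only; requesting it on show-coords input is reported as
a dialect mismatch rather than silently passing everything.

Per-pair cutoffs are a configuration concern: very close genome pairs (e.g.
two sibling species sharing ~99% identity genome-wide) are called at 99,
more distant pairs at 95, else the cutoff stops separating shared from
background regions.

### Coordinate conventions

All internal coordinates are 0-based half-open (BED convention).
show-coords 1-based inclusive input is converted on read (`start−1`, end
unchanged) and reconverted on write; reverse-strand query intervals are
stored forward-normalised with a strand flag.  Binning uses reference
coordinates only, so strand never affects block calls.  Half-open semantics
make adjacency zero overlap everywhere: in feature association, consensus
intersection and block disjointness alike.

### Numerical choices

- Medians use the standard sort-based definition (mean of the central pair
  for even counts) via `statistics.median`, then half-up rounding through
  `decimal` — Python's and numpy's native rounding are half-even, which
  would make the "identical median" comparison depend on the parity of the
  last digit.
- Feature-to-block ties (a feature overlapping two blocks equally) resolve
  to the leftmost block, after preferring the larger overlap.
- Degenerate inputs are defined, not errors: an empty alignment list yields
  a valid empty block set; an empty block set has coverage 0 and an
  undefined (null) mean length.
- Percent identity from PAF is `matches / block length × 100` (columns 10
  and 11); alignment tags are ignored.  Writing PAF quantises identity to an
  integer matches column; the show-coords writer round-trips identity
  exactly at full float precision.

## Confidence classifier

The decision rules are given in the README.  Non-obvious choices:

- The E-value threshold is 1e-10 and coverage threshold 95%, both strict
  (boundary values do not qualify); both are configurable.  One published
  variant of this rule family writes the threshold in a form that could be
  read as 1e-9; `evalue_max` is a parameter precisely so either reading is
  one flag away.
- The second HC clause (UniPoa support, no UniMag, no PTREP) requires a
  complete protein by default (`hc2_requires_complete`); the sentence
  structure of the published rule is ambiguous on this point, and the flag
  exposes the alternative reading.
- The rule is **not monotone** in evidence thresholds: because HC and LC
  clauses contain negated hits (no UniMag hit, no PTREP hit), *tightening*
  thresholds can disqualify a PTREP hit and thereby promote a REP protein to
  HC.  This is a property of the published rule, not an implementation
  artifact; the test suite documents the non-monotone branch and asserts the
  restrictions that do hold (hit qualification is monotone; an LC protein is
  never promoted).
- "TREP" and "PTREP" are accepted as names of the same database.

## Consensus NLRs

The catalogue is keyed on annotated gene models (the final lists users work
with are gene-based); a mirror mode emits the supported de-novo loci
instead.  Overlap is strand-agnostic by default because de-novo locus
predictors and gene annotation pipelines frequently disagree on strand for
the same locus; a strict-strand mode exists.  `min_overlap` defaults to the
1-bp intersection convention of the standard interval tools; whether a
fraction-based overlap would be more appropriate is study-dependent and the
parameter is exposed.

## Orthogroup algebra

Exclusive sharing is exact set equality: a group counts for genome set *S*
iff the genomes with ≥ 1 gene are exactly *S*.  Upset counts therefore
partition the groups and must sum to the group total (asserted in tests).
Single-copy selection is strict by default — a gene in any non-panel genome
disqualifies — matching the "exactly one copy in each of the nine diploid
genomes" reading after polyploid columns are split into subgenomes.
Subgenome splitting takes user-supplied regular-expression rules rather than
hard-coding any one gene-id grammar; every gene of a split genome must match
exactly one rule, and violations are reported with the offending ids.

## Synthetic data: what it does and does not emulate

The generators produce inputs in the exact dialects the pipeline reads, so
no code path can distinguish fixture from field data.  What they emulate:

- **Alignment tilings**: left-to-right tilings with length jitter and gaps,
  identity = planted tract target + Gaussian noise clipped to [0, 100], plus
  a configurable fraction of short decoy alignments below the length filter.
  Gaussian identity noise is a modelling choice (real identity dispersions
  are skewed and repeat-structured); the clip matters only at extreme
  settings.
- **Genome pairs** (desk scale, ≤ 10 Mb/chromosome): the query is the
  reference with per-tract uniform substitution at rate
  (100 − identity)/100, so an external aligner can be slotted in end to end.
  No indels, rearrangements or transposon landscapes are simulated.
- **Orthogroup tables** with exact planted exclusive-sharing counts;
  **protein evidence** sampled per truth label from the decision table with
  metrics on the correct side of every threshold; **NLR track pairs** with
  slot-based placement guaranteeing the planted overlap structure.

Default conditions: 5-Mb bins on 100-Mb chromosomes (20 bins), alignment
mean length 30 kb with 5-kb jitter and ≤ 5-kb gaps (~600 alignments and
~150 identity observations per bin), identity noise sd 0.1 percentage
points, background identity 90% against planted tracts of 97–99.5%, decoy
fraction 5%.  These give per-bin median standard errors of ~0.02–0.03
points: small against a 95% cutoff, but of the same order as the 0.01
rounding quantum — so identical-median mode may split a tract into several
adjacent passing blocks.  Recovery is accordingly measured at base level
(Jaccard of the called-block union against the above-cutoff truth union),
which is invariant to such splits.

Consequently, passing tests demonstrate correctness of the *algorithms*
(binning, merging, set algebra, intersection) and recovery under the stated
noise model — not robustness to structural variation, repeat-driven spurious
alignment, or reference bias, none of which the generators model.

Determinism: one master seed drives one named, CRC-derived stream per
generator, so outputs are byte-stable and adding a generator call never
perturbs another's draws.

## Known limitations

- Identity binning ignores alignment length beyond the filter; one long and
  one short alignment weigh equally in a bin median.
- Tract boundaries in the simulator align with the bin grid; real haplotype
  boundaries do not, and partial-bin tracts dilute the bin median.
- The genome-pair simulator's substitution-only model understates real
  divergence structure; it exists for end-to-end plumbing, not benchmarking
  aligners.
- Multi-genome intersection reports only intervals covered in *every* set;
  partial-coverage patterns require combining pairwise results.
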
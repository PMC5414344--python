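# Methods

This note records the quantitative definitions `binref` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make results
deterministic.

## Inputs and identifiers

A refinement run is keyed entirely by contig id — the FASTA header token
before the first whitespace, matching the convention of common binners so
assignment CSVs join cleanly. All tables (coverage, marker genes,
assignments) are id-keyed, never positional: permuting rows of any input
CSV changes no downstream number. Contigs missing from the coverage or
marker tables are treated as all-zero rows with a logged warning rather
than errors, because binners routinely drop short contigs. CSVs are
comma-delimited with `.` decimals; no locale sniffing.

The marker-gene CSV is accepted in two dialects, auto-detected: long form
(one row per predicted gene occurrence; duplicate rows aggregate to copy
counts) and wide form (contig × gene count matrix). The upstream
gene-prediction format varies between pipelines, so both are supported;
the auto-detection rule (wide iff all non-key columns parse numeric) is a
documented convention, not an assertion about any particular upstream
tool.

## Per-contig variables

**GC content** is (G+C)/(A+C+G+T); ambiguity codes are excluded from
numerator and denominator, and a contig with no unambiguous base reports
NaN.

**K-mer profiles** (k = 4 or 5) use sliding windows of step 1; a window
containing any non-ACGT character is skipped entirely rather than
fractionally distributed — simpler, and exactly testable against a naive
window count. Counts are divided by the number of valid windows.
Profiles are strand-collapsed by default (a k-mer and its reverse
complement share the lexicographically smaller label: 136 canonical
tetramers = 16 palindromes + 120 pairs; 512 canonical pentamers, no odd
palindromes), because assembled contigs have arbitrary strand; a flag
restores the raw 256/1024 space for workflows that want strand-specific
composition. Both variants are exposed since either convention appears
in composition-binning practice.

**DNA-RPKM** is reads/(length in kb)/(million mapped reads). It is
linear in the read count and invariant to scaling counts and totals
together; zero length or zero total is an error, not a NaN.

The feature matrix orders columns as abundances (input sample order),
GC, then k-mers in label order, each tagged with its kind so clustering
and selection can slice by kind.

## Correlation-threshold clustering

The clustering is a deterministic single-pass canopy with two
parameters: the correlation threshold *t* ∈ (−1, 1] (default 0.9) and
the minimal cluster size *m* ≥ 1 (default 5).

1. Unassigned contigs are ordered by descending mean profile value
   (ties by id) — high-abundance contigs have the best-measured
   profiles, so they make the most reliable seeds. An `id` order is
   available for strict reproducibility audits.
2. The first fresh contig seeds a candidate set: itself plus every
   unassigned contig whose correlation with the *seed profile* is ≥ *t*.
   Assignment is pinned to the seed — no centroid re-estimation — which
   keeps the pass deterministic and order-free.
3. The set commits as a bin iff it has ≥ *m* members; otherwise only the
   contig's *seed role* is spent — it remains eligible to join later
   bins, which maximises recall of small genomes.
4. Leftovers are labelled `unbinned`.

Pearson is the default correlation; Spearman (rank-transformed rows) is
offered for heavy-tailed profiles. At least five variables are required:
correlations over fewer sample values are too unstable to threshold.
Non-abundance variables (GC, k-mer frequencies) are z-scored before
being appended to the profile so one scale cannot dominate; abundance
columns enter raw, since Pearson is location/scale-free per pair. A
constant (zero-variance) profile has correlation defined as 0, with a
warning — such a contig can only self-bin at *m* = 1.

k-means (scikit-learn, k-means++ from a fixed seed, labels renumbered by
descending cluster size) is an assist for enlarging/narrowing selections
during refinement, not a primary binner.

## Ordination

**PCA** defaults to centred, *scaled* (correlation-matrix) form because
DNA-RPKM scales differ across samples with sequencing-depth artefacts; a
flag disables scaling. Eigenvalues are those of the covariance of the
processed matrix (denominator n−1). The contribution of a variable to an
axis is its squared loading (loadings are unit vectors, so axis
contributions sum to 1); an individual's contribution is its squared
score over the axis's total squared score.

**CA** consumes a non-negative contig × k-mer *count* table. When only
frequencies are available, counts are reconstructed as frequency ×
valid-window count — CA needs a contingency table with meaningful
margins. All-zero rows/columns are dropped with a warning. The
decomposition is the standard one (standardised residuals of P = N/n,
SVD, principal coordinates); total inertia equals the Pearson χ² of the
table divided by its grand total, which the tests verify against an
independent χ² computation to 1e-8. A 5000-row cap mirrors the display
limit interactive front ends impose; it is a named argument, so batch
analyses can raise it deliberately rather than silently.

Axis signs are canonicalised (the largest-|loading| variable entry on
each axis is made positive) so results are bit-reproducible across
LAPACK builds. Variable ranking weights each axis's contribution by its
explained fraction; scores are quantized at 1e-12 before the stable sort
so exact mathematical ties (for scaled PCA over all axes, every
variable's weighted total is identically 1/p) break by input order.

## Marker-gene quality

With summed copies c_g of gene g over a selection and universe size U
(default 109, a domain-level bacterial single-copy panel):
completeness = 100·|{g : c_g ≥ 1}|/U and contamination =
100·Σ max(0, c_g − 1)/U. The excess-copy contamination form is the
standard single-panel analogue of duplicate-marker counting; both
statistics are monotone non-decreasing as contigs are added, which the
suite checks as a property. The universe size, not the number of genes
actually predicted, is the denominator — an assembly missing markers is
incomplete, not smaller.

F1 uses recall = completeness and precision = 100 − contamination,
floored at 0 and forced to 0 outright when contamination exceeds 100
(beyond that point the selection contains more foreign than expected
marker content). F1 of a bin set is the mean of per-bin F1 values, not
the F1 of the means; method averages exclude bins the method never
assigned ("NB") from the denominator.

Category boundaries are closed on the left for completeness (Near is
[90, 100]) and closed at the upper edge for Low contamination
([0, 5]); 5.3 is Medium. These conventions reproduce the bundled
campaign tables exactly.

Binning comparison uses the adjusted Rand index over contigs assigned by
*both* methods, so differing unbinned fractions do not dilute agreement;
a brute-force pair-counting ARI serves as the test oracle.

## Refinement sessions

Selections are conjunctions of predicates — closed numeric intervals on
feature variables, label sets on assignment columns — resolved against
the session's working set. Keep/remove reshape the working set only;
the underlying tables are never truncated, so unbinned contigs stay
exportable. Edits live in a dedicated `refined` column seeded from any
chosen source binning, leaving inputs immutable. Union gestures from
interactive tools are deliberately absent; unions are achievable as
multiple assigns.

Every mutating operation appends an event (index, timestamp, operation,
resolved contig ids, affected count) to an append-only audit log.
Events store *resolved ids* rather than predicates, so replay is exact
even if the feature matrix is absent or has changed; replaying a
truncated log yields the intermediate state at the truncation point. An
order-independent SHA-256 over the refined column supports end-to-end
replay verification. The exported session state (schema-versioned JSON)
carries the feature slice, assignments, working set, tags and log.

## Synthetic communities

The generator emulates exactly the two signals the workflow assumes.
Composition: each genome draws i.i.d. bases (order-0 Markov) at its GC
target, with a genome-specific asymmetry in how each complementary pair
splits (A vs T, G vs C), giving distinct tetramer signatures at
identical GC; an order-2 hook produces harder fixtures. Abundance: each
genome has a lognormal mean profile across samples (log-sd 2.5 —
abundances swinging two to three orders of magnitude across a time
series, as in succession-driven communities), drawn with pairwise
|r| ≤ 0.6 between genomes so planted co-abundance structure is distinct
by construction; per-contig, per-sample multiplicative lognormal noise
(default σ = 0.2) corrupts it. Defaults (10 genomes × 30 contigs,
7 samples, lengths ≥ 1000 nt, 109 markers each placed on exactly one
contig of its genome, optional duplication rate to plant contamination)
are the study conditions the test suite exercises; under them the
correlation clustering recovers the planted partition with adjusted Rand
index ≥ 0.9 at t = 0.9, m = 5.

Not emulated: read-level sequencing error, assembly artefacts and
chimeras, strain mixtures, horizontal transfer, GC-dependent coverage
bias, and between-sample compositionality. Passing tests therefore
demonstrate algorithmic correctness on data satisfying the method's own
assumptions, not performance on real assemblies.

## Problem sizes and determinism

The test suite runs small fixtures (hundreds of contigs, sequences of
1–3 kb) chosen so the full suite completes in seconds while still
exercising every code path; the planted-partition check uses the full
default community (300 contigs, 7 samples). All randomness flows through
seeded `numpy` generators; a fixed seed yields byte-identical generated
files. The bundled campaign summaries are deterministic arithmetic over
the shipped tables.

## Known limitations

* Completeness/contamination use a single domain-level marker panel;
  lineage-specific marker sets (as in CheckM) would be more sensitive
  for well-placed genomes, and archaeal or eukaryotic bins are outside
  the panel's scope.
* Contamination counts excess copies linearly; it does not distinguish
  one gene at 5 copies from four genes at 2.
* The canopy pass is single-threshold and seed-pinned; it will split a
  genome whose abundance profile drifts across the threshold, and it
  does not re-estimate centroids.
* CA on k-mer counts treats contigs as independent rows; long and short
  contigs are weighted by their window counts (row masses), so a few
  very long contigs can dominate axes.
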
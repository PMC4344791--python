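# Methods

This note documents the models and procedures implemented in `wheattf`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions.

## Sequence identity and clustering

Pairwise identity follows the cd-hit convention: the number of identical
aligned positions in the best local alignment, divided by the length of
the shorter sequence. The local aligner is an affine-gap Smith-Waterman
(Gotoh recurrence) with match +1, mismatch −2, gap open 2 and gap extend
1, so a gap of length *g* costs 2 + *g*. `X` and `N` never score as
matches and never count as identical positions. Tie-breaks are
deterministic: the best-scoring cell with the smallest (query end,
subject end) wins, and traceback prefers diagonal over vertical over
horizontal moves.

Greedy clustering processes sequences longest-first (ties by input
order); each sequence joins the first existing cluster whose
representative it matches at ≥ the threshold, else founds a new cluster.
Because of the ordering, representatives are always the longest member.
The shared-k-mer prefilter (word sizes 8 nt / 5 aa, mirroring cd-hit's
`-n`) only applies at thresholds ≥ 0.95 and only skips pairs sharing no
k-mer at all; it is an advisory speed-up — the unit and acceptance tests
verify the clustering against a brute-force all-pairs replay with the
filter disabled.

"Redundant" sequences are counted as non-representative members (total
sequences minus clusters). For multi-set comparisons, the pooled
sequences are clustered and every sequence in a cluster mixing two or
more source sets counts toward the combination. Counts are non-increasing
in the threshold; this is asserted as an invariant.

## ORF search and translation

ESTs are fragments: the translator returns all maximal stop-free
stretches of ≥ `min_orf_aa` (default 30) residues in the six reading
frames, with no start-codon requirement, and the pipeline keeps one best
protein per record (longest; ties broken by frame order +1, +2, +3, −1,
−2, −3, then smaller start coordinate). Codons containing `N` translate
to `X`, which is excluded from identity counts downstream. This
deliberately replaces a coding-potential model (the classical tool for
this step is framefinder): the longest-stretch heuristic is deterministic
and dependency-free, and is adequate whenever genuine coding regions
dominate ORF length — which the tests verify on the synthetic corpora,
and which cannot be assumed for low-quality real ESTs with indel errors.

## Profile HMMs and E-values

Each family is modelled by a "Plan7-lite" profile HMM: position-specific
match emissions, one shared insert emission distribution (equal to the
background), per-state transition probabilities over {M→M, M→I, M→D,
I→M, I→I, D→M, D→D}, and Smith-Waterman-style local alignment (free
entry into and exit from any match state; flanking residues are
background-emitted and cancel out of the log-odds). There is no multi-hit
state: the pipeline only needs one best domain per protein per family.

Profile estimation from a seed alignment: columns with gap fraction
< 0.5 become match states; emissions are additively smoothed,
(count + 1) / (non-gap count + 20); transitions are estimated from the
per-row observed state paths, pooled across positions, with the same
smoothing; the background is the smoothed overall residue frequency of
the seed. Scores are Viterbi log-odds in bits. The Viterbi DP is
vectorised along the match-state axis, with the delete-state recursion
rewritten as a running maximum; it is verified against exhaustive
enumeration of all legal state paths on small instances.

E-values use a Gumbel fit to Viterbi scores of random
background-composed sequences (default 200 sequences of length 100):
λ = π/(σ√6), μ = mean − γ/λ (method of moments), and
E(s) = N·exp(−λ(s−μ)) clamped to [0, N], where N is the number of
scanned proteins. This is a declared stand-in for HMMER's calibrated
statistics, not a claim of equivalence; its self-consistency (the
empirical tail probability at the Gumbel's 1% point is ≈ 1%) is tested.
The hit threshold is E < 0.01.

A practical note on seed depth: with very shallow seed alignments the
additive smoothing flattens match emissions (a mismatch at a perfectly
conserved column of an 8-row seed costs only ~0.5 bits) and the
seed-derived background becomes noisy enough that E-values turn
anti-conservative. Real curated DBD seed alignments hold tens to hundreds
of sequences; the synthetic generator therefore defaults to 30 rows per
seed, which restores sharp emissions, a stable background, and an
order-of-magnitude margin between true-domain scores (~100+ bits) and the
chance-hit regime (~20 bits).

## Family assignment

A family rule lists required domain sets (AND across sets, OR within a
set) and forbidden domains (veto). A protein's candidate families are all
rules satisfied by its domain-hit set; multi-family candidates resolve to
the family with the highest diagnostic bit score, ties going first to the
more specific rule (fewer total domains) and then to the
lexicographically smallest name. Resolution uses bit scores rather than
E-values to avoid calibration noise. Families with zero assigned TFs are
pruned from the catalog (and reported). TF identifiers are minted as
`TaTF` + five digits in (family, source id) order, so reruns on identical
input give identical ids. The shipped rule set covers only the synthetic
families; a real family rule table is a user-supplied JSON input.

## Specificity, validation, recovery

Presence matrices have one row per TF and seven 0/1 columns per axis —
six informative categories plus a catch-all ("unclear" stage / "other"
tissue) last. Classification: *specific* iff exactly one informative
column is set (the catch-all is ignored for this test, so
specific-plus-catch-all still counts as specific); *unclear* iff only the
catch-all is set; *unspecific* otherwise. The three classes partition the
catalog.

The pipeline initialises each TF's presence from its own source record's
library. Information held by other sequences then arrives through two
audited channels, each appending to a change log:

* **Matched-subject validation** — each putative specific TF's source EST
  is aligned against a subject EST set; subjects passing all three
  matched-sequence criteria (alignment length / query length strictly
  > 0.95, identity ≥ 0.80, subject strictly longer than the query) donate
  their library's category.
* **Filtered-sequence recovery** — sequences removed by redundancy
  clustering are independently translated and domain-scanned; those that
  are themselves TFs, and whose cluster representative is an identified
  TF, donate their categories to the representative.

Both operations only ever set bits, so the specific count is
non-increasing through validation, updates are idempotent, and replaying
the change log from the initial matrices reproduces the final matrices
exactly — all asserted as invariants. The matrix-building operation
itself is generic over any cluster structure (cell(tf, c) = 1 iff any EST
of the TF's cluster comes from a library of category c), so callers can
also aggregate presence over whole clusters directly.

Venn tabulation reports counts for all 127 non-empty membership patterns
over the seven categories plus per-category totals; rendering the
rotationally symmetric 7-set diagram is out of scope.

## Category mapping

Library labels map to categories by exact keyword lookup after
case-folding and whitespace-stripping — substring matching is not used
(so "germinating seedling trial" does not silently match "seedling").
Unrecognised, empty, mixed or unclassified labels fall into the
catch-all. Each library maps to exactly one stage and one tissue; per-EST
overrides are not supported. The default keyword tables encode the
standard groupings (inflorescence → flower, sheath → leaf; callus, cell
culture, whole plant, mixed tissue → other); users extend them through
the `overrides` mapping.

## Synthetic data: what it emulates, and what it does not

The generator plants, per configuration: family seed alignments over
conserved protein cores (70% of core columns frozen, ≥ 60% fully
conserved columns, pairwise core identity ≤ 40%, two low-occupancy insert
columns); TF transcripts carrying a back-translated, optionally mutated
copy of a family core inside random non-stop UTR codons (so the planted
ORF is the longest stop-free stretch by construction); near-identical
duplicates (identity ≥ 0.95, mutations avoiding sequence ends and the
domain's first/last three codons, and never creating an in-frame stop);
a stage × tissue grid of libraries plus a catch-all; and two validation
scenarios — a near-identical longer subject EST from a different category
(blast-update) and a duplicate whose extra category survives only in the
filtered-out set (filtered-recovery). The truth table encodes the final,
post-update/post-recovery presence per EST, so end-to-end runs are
compared bit for bit.

Defaults (the study conditions used by the tests and the acceptance
script): 3 families, 50-residue cores, 30-row seeds, 30 TF transcripts,
20 background sequences, duplicate rate 0.2 at identity 0.97, domain
mutation rate 0.03, 80% of TFs planted specific, one scenario of each
kind. These sizes keep a full pipeline run around ten seconds while
exercising every stage.

Deliberately not emulated: wheat codon usage (back-translation uses one
fixed common codon per amino acid, removing codon randomness from
family-recovery tests); homoeologous A/B/D gene copies; sequencing-error
indels; realistic EST length and quality distributions; correlated
library sampling. Background sequences are i.i.d. uniform nucleotides
with no ORF-length control, so the scanner's false-positive rate on them
is itself a measured property. Passing tests therefore demonstrate the
pipeline's correctness and internal consistency, not its sensitivity or
specificity on real EST data.

## Numerical conventions and edge cases

* Percentages are rounded half-up (not banker's) to two decimals.
* Log-space DP throughout; −∞ is a sentinel (−1e30) below any legal score.
* Probability tables must normalise to 1 within 1e−9 (validated on
  construction).
* Empty corpus: the pipeline runs to completion with all-zero waypoints.
* Zero-variance calibration scores (e.g. a flat profile) raise instead of
  fitting a degenerate Gumbel.
* Sequences with characters outside {A, C, G, T, N} are rejected at load
  time, not sanitized.
* All randomness flows from explicit integer seeds; identical inputs and
  seeds give byte-identical outputs.

## Known limitations

* The greedy clustering is quadratic in the number of clusters per query
  and meant for desk-scale corpora, not for hundreds of thousands of
  ESTs; the k-mer prefilter mitigates but does not change the complexity.
* The Gumbel method-of-moments calibration is less accurate in the
  extreme tail than a maximum-likelihood or empirical fit; E-values near
  the threshold should be treated as approximate.
* One best protein per EST means a chimeric EST with two genuine ORFs
  contributes only its longer one.
* The matched-subject search aligns every query against every subject;
  there is no seeding heuristic, so large subject sets are slow.
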
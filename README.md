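# wheattf

Identification of transcription factors (TFs) from EST collections, and
classification of each TF as developmental-stage-specific,
tissue-specific, unspecific, or unclear.

## The problem

Expressed sequence tags (ESTs) are single-pass cDNA reads; each carries
the annotation of the library it was sequenced from — which tissue, and at
which developmental stage, the mRNA was sampled. For a crop like hexaploid
wheat, where genome annotation lags behind, EST collections are the
practical route to a genome-wide TF catalog: a protein is called a TF when
it carries a diagnostic DNA-binding domain (DBD), and its family (MYB,
ERF, NAC, WRKY, ...) is defined by which DBD it carries.

`wheattf` implements that workflow as a tested, reusable library:

1. **Redundancy clustering** of nucleotide ESTs — greedy incremental
   clustering in the cd-hit style (longest sequence first, identity to the
   representative ≥ threshold, default `-c 0.95`), with identity defined
   as identical aligned positions in the best local alignment divided by
   the shorter sequence's length.
2. **Six-frame translation** — one best protein per EST, the longest
   stop-free stretch of ≥ 30 residues across all six frames (EST fragments
   lack start codons, so no Met is required).
3. **Protein-level clustering** at 0.95 identity.
4. **Profile-HMM domain scan** — per-family profile HMMs built from seed
   alignments (match/insert/delete states, Laplace-smoothed emissions),
   scored by local Viterbi in bits, with E-values from a Gumbel
   distribution fitted to random-sequence scores by the method of
   moments. A protein with a domain hit at E < 0.01 is a TF candidate.
5. **Family assignment** — PlantTFDB-style rules (required domain sets
   AND-ed, OR within a set, forbidden domains veto); multi-family
   candidates resolve to the highest-scoring diagnostic domain; empty
   families are pruned from the catalog.
6. **Specificity classification** — a 7-slot presence vector per axis
   (six informative categories plus a catch-all). A TF expressed in
   exactly one informative stage (or tissue) is *specific*; in none, with
   only the catch-all set, *unclear*; otherwise *unspecific*.
7. **Validation and recovery** — putative specific TFs are checked
   against a subject EST set: a *matched* subject (alignment covering
   > 0.95 of the query, identity ≥ 0.80, subject strictly longer) donates
   its library's category to the query. Sequences removed by clustering
   are re-scanned, and those that are themselves TFs donate their
   categories to their cluster representative.

A synthetic-data module generates corpora with planted ground truth
(family membership, duplicates, specificity, validation/recovery
scenarios) so the full pipeline is testable end to end without external
databases.

## Worked example

```python
from wheattf import (SyntheticConfig, PipelineConfig, generate_corpus,
                     run_pipeline)

corpus = generate_corpus(SyntheticConfig(rng_seed=1))
result = run_pipeline(
    PipelineConfig(rng_seed=1),
    corpus.est_records, corpus.library_annotations,
    corpus.seeds, corpus.rules, corpus.subject_records,
)
r = result.run_report
print(r["n_input_ests"], r["n_nt_clusters"], r["n_tfs"],
      r["n_stage_specific"], r["n_validation_changes"],
      r["n_recovery_changes"])
```

prints

```
54 50 30 22 2 2
```

54 input ESTs collapse to 50 non-redundant sequences (4 near-duplicates
removed); all 30 planted TF transcripts are identified and assigned to
their true families; 22 end up stage-specific. The two validation changes
are the planted near-identical subject EST from a different library
flipping one specific TF to unspecific, and the two recovery changes are a
clustered-away duplicate donating its stage and tissue category back to
its representative. The first catalog row looks like

```
TaTF00001  FAM01  stage_presence [1, 1, 0, 0, 0, 0, 0]  stage_specific False
```

— a TF seen at two developmental stages, hence not specific.

The same flow is available from the shell:

```sh
wheattf simulate --seed 1 --out-dir sim/
wheattf run --est sim/est.fasta --libraries sim/libraries.tsv \
    --seeds-dir sim/seeds --rules sim/rules.json \
    --subjects sim/subjects.fasta --out-dir out/ --seed 1
```

which writes `tf_catalog.tsv`, `tf_proteins.fasta`, `tf_nucleotides.fasta`,
`summary.json` and `run_report.json`.

## Layout

```
src/wheattf/
  corpus.py       EST/library IO, stage & tissue category mapping
  synthetic.py    corpus generator with planted ground truth
  redundancy.py   Smith-Waterman identity, greedy clustering, cross-set tables
  orf.py          six-frame ORF search and translation
  hmm.py          profile HMM build / Viterbi / Gumbel E-values / scan
  families.py     family rules, assignment, resolution, TF ids
  specificity.py  presence matrices, specificity flags, tables, Venn counts
  validation.py   matched-alignment validation and filtered-seq recovery
  reporting.py    pipeline orchestration, export, percentage arithmetic
  cli.py          click CLI (simulate / cluster / translate / scan /
                  classify / report / run)
```

See `docs/methods.md` for the model details, parameter choices and
limitations.
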
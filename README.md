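# venomexome

A tested, reusable pipeline for discovering venom-gland-specific
transcripts (VSTs) and candidate toxins from a three-tissue
transcriptome (venom gland, silk gland, cephalothorax), plus a seeded
synthetic-data generator so every stage is verifiable against planted
ground truth without external data.

Stages:

1. **synthetic_data** — seeded toy transcriptome bundles: transcript
   FASTA (truth proteins encoded in frame +1 between UTRs),
   negative-binomial count tables, homology annotations, GO
   assignments, signal-peptide calls, and in-silico tryptic peptide
   identifications with decoys. Planted venom-specific families are
   either short 8-cysteine knottin-like proteins or long
   ankyrin-repeat proteins.
2. **orf_tools** — six-frame stop-to-stop ORF enumeration (≥ 90 nt,
   N-containing codons → X) and best-protein selection: longest ORF in
   the best-hit frame, else longest overall, overridden by a
   stop-bounded M-start ORF when it reaches 75% of the longest ORF.
3. **redundancy** — collapse of proteins identical over their entire
   region of overlap (substring containment, single linkage), keeping
   the longest (ties: first) member.
4. **tissue_specificity** — eCPM and FPKM layers; VST classification by
   exclusive expression (venom eCPM > 1, zero elsewhere) or by both
   venom/silk and venom/cephalothorax eCPM ratios reaching the upper
   2.5% nearest-rank cutoffs of the remaining transcripts, with
   ≥ 1 venom eCPM.
5. **toxin_screens** — keyword category tagging (YAML-configurable,
   e-value gated at 1e-5), the small/cysteine-rich screen (< 200
   residues, ≥ 6 cysteines, M-start), cysteine-framework extraction
   with a rule-based knottin candidacy check, and category-wise
   expression summaries.
6. **family_clustering** — deterministic optimal local alignment
   (BLOSUM62, affine gaps 11/1) and single-linkage clustering across a
   30–95% identity × coverage grid (coverage must hold for both
   sequences).
7. **go_enrichment** — length-bias-corrected GO overrepresentation:
   binned, isotonic-smoothed selection weights, weighted resampling
   nulls (Gumbel top-k sampling without replacement), BH FDR.
8. **proteome_integration** — peptide-to-protein placement (I/L
   equivalent), the > 95% probability / ≥ 2 unique-peptide confirmation
   filter, percent coverage, and the VST × signal-peptide secretome
   cross-tab.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (independent
oracles, planted-truth recovery, calibration, determinism), one test
per criterion.

## CLI

```sh
# generate a synthetic bundle with known ground truth
venomexome simulate --out bundle/ --seed 1

# run everything (writes tables + manifest.json to run/)
venomexome all --indir bundle/ --out run/ --seed 1

# or stage by stage
venomexome orfs --fasta bundle/transcripts.fasta \
    --annotations bundle/annotations.tsv --out orfs/
venomexome collapse --proteins orfs/proteins.fasta --out nr/
venomexome specificity --counts bundle/counts.tsv --out spec/
venomexome screen --proteins nr/nonredundant.fasta \
    --signal bundle/signal.tsv --annotations bundle/annotations.tsv \
    --out screen/
venomexome cluster --proteins nr/nonredundant.fasta --out sweep.tsv
venomexome enrich --go-table bundle/go_terms.tsv --counts bundle/counts.tsv \
    --specificity spec/specificity.tsv --out enrichment.tsv
venomexome proteome --peptides bundle/peptides.tsv \
    --proteins nr/nonredundant.fasta --out evidence.tsv
```

Identical config + seed reproduces byte-identical outputs; every run
writes a JSON manifest with parameters and input checksums.

## Input formats

All inputs are plain text: FASTA for sequences and tab-separated tables
with a header row — counts (`transcript_id, venom, silk, ceph,
effective_length_nt`), annotations (`transcript_id, hit_description,
evalue[, hit_frame]`), GO (`transcript_id, go_id`), signal calls
(`protein_id, has_signal, cleavage_pos`), and peptide identifications
(`peptide_seq, peptide_prob, protein_prob`).
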
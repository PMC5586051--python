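# srnapipe

Plant small-RNA analysis, from raw sequencing tags to degradome-validated
miRNA targets.

`srnapipe` is aimed at researchers analysing bulk small-RNA sequencing of
plant tissues (the motivating use case is cereal embryo development and
germination). It reimplements, as a tested and reusable library plus CLI,
the classic plant miRNA survey workflow:

1. **Read cleaning** — drop low-quality reads and 5′-adaptor contaminants,
   trim 3′ adapters, keep 18–30-nt inserts, collapse identical reads into
   tags with per-library counts.
2. **Tag classification** — ordered exact matching against rRNA / tRNA /
   snRNA / snoRNA / repeat / exon / intron references (first class in
   priority order wins; non-coding matches are discarded from miRNA
   calling).
3. **Known miRNAs** — a tag is a known miRNA when it is an exact
   substring of a same-species precursor, shares an ungapped, mismatch-free
   overlap of ≥ 16 nt with a same-species mature, or matches any plant
   mature/precursor with ≤ 2 pooled mismatches-or-gaps *and* has a
   verifiable fold-back precursor at its genomic locus.
4. **Novel miRNAs** — candidate precursors are excised around each
   genome-mapped tag (±250-nt flanks), folded with a built-in
   nearest-neighbor stacking DP (or imported RNAfold structures), and
   accepted when the mature sits on one arm of a stem-loop (≤ 4 unpaired
   bases) opposite a star across a single terminal loop, with

   MFEI = (−MFE / L × 100) / GC% ≥ 0.9.

5. **Expression** — TPM = count / total clean reads × 10⁶; differential
   expression between two libraries by the Audic–Claverie tag-count test
   (or Fisher's exact test), significant when |log₂(treatment/control)| ≥ 1
   and p < 10⁻⁵.
6. **Target prediction** — every transcript window is scored as an
   antiparallel ungapped duplex under the six plant complementarity rules
   (≤ 4 mismatches with G·U = 0.5; no >2 consecutive mismatches; no
   adjacent mismatches in positions 2–12; no mismatch at positions 10–11;
   ≤ 2.5 mismatches in positions 1–12; duplex MFE ≥ 75% of the perfect
   duplex).
7. **Degradome validation** — PARE 5′ tags are mapped exactly to
   transcripts; a site is validated when a peak of ≥ 2 reads falls within
   ±1 nt of the expected slicing coordinate, **site end − 9** (the bond
   opposite miRNA positions 10–11), with CleaveLand-style categories 0–4.
8. **Enrichment** — upper-tail hypergeometric test of term assignments in
   target genes against the transcript background; ΔΔCt relative
   quantification (2^−ΔΔCt) for qPCR follow-up.

A first-class synthetic-data generator plants known truths for every
stage — hairpins, dinucleotide-shuffled decoys, rule-compliant and
rule-violating binding sites, and degradome peaks at end − 9 over Poisson
noise — so the entire pipeline is testable without downloads.

## Worked example

Generate a synthetic cohort (10 planted hairpins, 10 shuffled decoys,
two 20,000-read libraries) and run all stages:

```bash
srna-pipeline simulate --out demo --seed 7 --hairpins 10 --decoys 10 --depth 20000
cat > demo.yaml <<EOF
output_dir: demo_run
srna_libraries:
  libA: demo/srna_libA.fa
  libB: demo/srna_libB.fa
genome_fasta: demo/genome.fa
transcripts_fasta: demo/transcripts.fa
degradome_tags: demo/degradome.tsv
term_table: demo/terms.tsv
EOF
srna-pipeline run --config demo.yaml
```

The manifest (`demo_run/manifest.json`) records the per-stage row counts:

```
"row_counts": {
    "preprocess": 32017,   # distinct tags across both libraries
    "novel": 10,           # all 10 planted hairpins recovered
    "de": 10,              # miRNA features tested libA vs libB
    "target": 20,          # six-rule binding sites on the transcripts
    "degradome": 20,       # sites with a PARE peak at end - 9
    "enrich": 10           # terms tested on the target genes
}
```

`demo_run/validated_sites.tsv` shows the site geometry — every validated
cut coordinate equals site end − 9, e.g. a perfect-complement site at
200–220 cut at 211, confirmed by a unique degradome maximum (category 0):

```
miRNA             transcript  start  end  cut  mismatches  energy_ratio  validated  category
novel:GGCGCTCG    tx1         200    220  211  0           1.0000        yes        0
novel:GCGCTGCT    tx10        200    220  211  0           1.0000        yes        0
```

`demo_run/de.tsv` reports the tag-count test; here a miRNA planted at
~4-fold lower abundance in libB is called significant
(log₂FC = −2.08, p = 7×10⁻³⁶), while a 1.7-fold change is not:

```
feature           count_libA  count_libB  tpm_libA  tpm_libB  log2fc  p_value   significant
novel:AATACGAC    302         523         15100.00  26150.00  0.792   1.03e-14  no
novel:ACCTGGTG    309         73          15450.00  3650.00   -2.082  7.2e-36   yes
```

Every stage is also available as a library call
(`srnapipe.scan_transcript`, `srnapipe.call_novel`, `srnapipe.de_test`,
…) and as an individual subcommand (`preprocess`, `annotate`, `novel`,
`target`, `degradome`, `de`, `enrich`, `simulate`).

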
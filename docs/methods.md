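# Methods

This note documents the models and procedures implemented in `srnapipe`,
the defaults and why they were chosen, what the synthetic benchmark does
and does not show, and the package's known limitations.

## Data model and conventions

All sequences are stored internally in the DNA alphabet (U → T on
input); conversion back to RNA happens only at display and energy
boundaries, so no stage can suffer a U/T mismatch. All coordinates are
1-based inclusive. The unit of quantification is the *tag*: a distinct
sequence with per-library read counts; identical reads are collapsed on
input and never expanded again.

## Read cleaning

Filters apply in order: quality → 5′ adaptor → 3′-adapter trim → N
content → length (defaults 18–30 nt). "Low quality" has no universal
definition for collapsed public data, so the contract is explicit:
discard a read when any base has Q < 20, a no-op for FASTA input.
Adapter handling is deliberately simple — exact prefix match for the 5′
adaptor (contaminants are discarded, as a read *starting* with the
adaptor carries no insert), seeded (first 8 nt) suffix search for the 3′
adapter — because vendor pipelines differ and both sequences are plain
config values. Per-rule removal counters satisfy
kept + Σ removed = input, which the pipeline manifest exposes for audit.

## Tag classification and known miRNAs

Classification is ordered exact substring matching (forward or reverse
complement — genomic tags are strandless) against per-class reference
sets; the first class in priority order (rRNA, tRNA, snRNA, snoRNA,
repeat, exon, intron) wins, making the assignment a partition. No
covariance-model scanning is attempted; classification quality is
limited by the supplied references.

Known-miRNA calling is stranded (matures are single-stranded) and
applies three rules in strict precedence:

1. *precursor_exact* — tag is an exact substring of a same-species
   precursor;
2. *overlap ≥ 16* — some ungapped alignment offset places a contiguous
   run of ≥ 16 matching positions between tag and a same-species mature.
   The mismatch budget inside the run is 0 by default and exposed as
   `overlap_mismatches`, since published descriptions of this rule do
   not state a budget and zero is the strictest reading;
3. *cross-species ≤ 2* — Levenshtein distance (mismatches and gaps
   pooled, computed with edlib; global against matures, infix against
   precursors) ≤ 2 to any other-species entry, accepted only when a
   fold-back precursor is verifiable at the tag's own genomic locus
   (geometry check below, no MFEI gate). Without a genome this rule is
   skipped rather than fired unverified.

## Hairpin folding and the novel-miRNA call

Candidate windows are excised at each exact genomic locus of a tag:
[start − 250, end + 20] and [start − 20, end + 250], clipped to the
chromosome, both strands.

The built-in folder is a Nussinov-style dynamic program that minimizes
the sum of stacked-pair free energies over nested, pseudoknot-free
structures: Watson–Crick and G·U pairs only, minimum hairpin loop 3,
stack energies from the published Turner-lab nearest-neighbor tables
(Watson–Crick stacks from Xia et al. 1998; G·U stacks from Mathews et
al. 1999, with the destabilizing G·U-on-U·G motif). Loop, bulge and
multiloop penalties are *not* modeled, so absolute MFEs are optimistic
relative to full Zuker folding; the same table also scores miRNA/target
duplexes, which keeps every energy *ratio* model-consistent. Users who
need exact thermodynamics can import RNAfold output; the parser accepts
the standard sequence / dot-bracket "( −1.20)" interleaving and the
`fold()` entry point prefers supplied structures. Traceback breaks ties
toward unpaired positions, so zero-contribution isolated pairs are never
reported. The O(n³) fill is JIT-compiled with numba (pure-Python
fallback retained).

A tag is called a novel miRNA when some excised window satisfies all of:

- mature wholly on one arm, ≤ 4 unpaired mature bases;
- a star region exists across a single terminal loop, with the canonical
  2-nt 3′ overhang geometry;
- the mature/star duplex bulges the star arm by ≤ 4 nt and the terminal
  loop spans ≤ 35 nt (Mireap-style precursor limits; scattered pairing
  over distant helices is not a miRNA/miRNA* duplex);
- precursor MFEI ≥ 0.9, with MFEI = AMFE / GC%, AMFE = −MFE/L × 100.

MFEI is computed on the *trimmed precursor* (the mature…star span, not
the raw ±250-nt window): the index characterizes pre-miRNAs, and
averaging −MFE over a fixed-width window of mostly background would
dilute it toward the genome baseline. Because the stacking-only model
yields systematically lower MFEs than full folding, absolute MFEI values
are not comparable with literature numbers computed under RNAfold; all
acceptance logic therefore rests on planted-truth recovery rather than
literature MFEI values. Ties between passing windows break toward lower
MFE. The pipeline additionally requires ≥ 5 supporting reads (config
`min_novel_reads`) before testing a tag.

## Target prediction

Duplexes are antiparallel and ungapped: miRNA position i (from the 5′
end) faces site position L − i + 1. The six rules use Allen-style
scoring: G·U counts 0.5 toward the totals of rules 1 and 5 but is
treated as a pair — not a mismatch — for the adjacency/position rules 2,
3 and 4; setting `gu_is_mismatch` selects the stricter alternative.
Bulged duplexes are out of scope (the rules mention only mismatches, and
gap support would require an unstated scoring). Rule 6 compares the
duplex energy with the energy of the miRNA bound to its exact reverse
complement, both under the embedded stack table, so the 0.75 threshold
is self-consistent. All passing windows are reported without
non-maximum suppression; degradome validation disambiguates overlapping
candidates. The expected slicing coordinate of a site [start, end] is
end − 9, the bond opposite miRNA positions 10–11.

## Degradome validation

PARE 5′ tags (≥ 15 nt) map to transcripts by exact sense-strand
matching only — degradome tags derive from the cleaved mRNA itself — and
multi-mapping tags increment every locus, so tag mass is conserved as
Σ profile totals = Σ (count × loci). A site validates when the maximum
count within ±1 nt of the expected cut (window config-exposed;
1 nt absorbs mapping ambiguity) is ≥ 2 reads (`min_reads`; the
literature states no universal threshold, 2 excludes singletons).
Peaks carry the de-facto standard categories: 0 unique transcript
maximum, 1 tied maximum, 2 above the median of nonzero positions,
3 otherwise with > 1 read, 4 singleton. Off-site positions at least as
abundant as the on-site peak are reported as secondary peaks.

## Expression statistics

TPM = count / total clean reads × 10⁶, where the denominator is the
library's clean-read total (not the surviving-feature column sum), so
TPMs of a filtered feature subset do not inflate. Fold change is
log₂(treatment/control) with a 0.01-TPM floor applied to the fold change
only, never to the test. The default two-library test is
Audic–Claverie — the canonical tag-count statistic for un-replicated
SAGE-style libraries — in negative-binomial form: the posterior of the
second count given the first is NB(x + 1, N₁/(N₁+N₂)); the two-sided p
is min(1, 2·min(lower, upper tail)), symmetrized by taking the min over
both conditioning directions so that swapping libraries cannot change
the verdict. Fisher's exact test on the 2×2 count table is the
alternative. A feature is significant only when both |log₂FC| ≥ 1
(linear two-fold; "fold change of at least 2" is read on the linear
scale, as requiring log₂FC ≥ 2 would contradict common usage — the
threshold is a config value) and p < 10⁻⁵. No multiplicity correction is
applied to DE calls (fixed per-feature cutoff); enrichment reports raw
hypergeometric upper-tail p-values with an optional Benjamini–Hochberg
column, and ΔΔCt quantification is 2^−ΔΔCt against a calibrator.

## Synthetic benchmark: what it shows and what it does not

The generator emulates the statistical structure of a plant embryo
small-RNA experiment: a 24-nt-dominant length distribution with a 21-nt
secondary population; 21-nt matures on stem-loop precursors (~32-bp
stems ≥ 80% Watson–Crick with three G·U wobbles, 8-nt loops, either
arm) spaced wider than the excision flank in i.i.d.-uniform background;
decoys as dinucleotide-shuffled precursors (random Eulerian walk)
whose mature-slice 21-mer is planted in the libraries at decoy
abundance; binding sites that are perfect, mildly degraded (≤ 1 mismatch
plus ≤ 1 G·U in the 3′ half) or that each violate exactly one of rules
1–4; and degradome tags whose 5′ ends sit exactly at site end − 9
(50 reads by default) over per-position Poisson(0.1) noise. All
generators are pure functions of (parameters, seed).

Passing the planted-truth suite (≥ 90% hairpin recall, ≤ 10% decoy
acceptance, ≥ 90% site-validation recall, ≤ 5% noise-only validation;
default problem sizes 50 + 50 hairpins and 20 + 20 sites, chosen to
give stable proportions at desk scale) demonstrates that the method's
*decision logic* is correct and well-calibrated. It does not demonstrate
performance on real data: real genomes have repeat structure and biased
composition, real libraries carry sequencing errors, isomiRs and RNA
modifications, and real degradome signal is diffuse — none of which the
generator models.

## Numerical choices and degenerate inputs

- Folding requires windows ≥ 40 nt ("window too short" otherwise);
  trimmed precursors are padded to 40 nt before refolding.
- Traceback equality uses a 10⁻⁶ tolerance; energies are reported to
  0.01 kcal/mol.
- MFEI is undefined for GC = 0 (error) and 0 for MFE = 0.
- The destabilizing G·U/U·G stack is clipped at 0 in duplex scoring so
  degrading a duplex can never *lower* its energy (monotonicity).
- Validation-peak ties resolve toward the position nearest the expected
  cut, then the smaller coordinate; site reports sort by (transcript,
  start) for byte-identical reruns.
- Empty libraries, all-zero profiles and empty site lists are valid
  inputs yielding empty outputs.
- MFEI strand symmetry is exact only for Watson–Crick pairing (the
  reverse complement of a G·U pair is unpairable C·A), so the symmetry
  property is guaranteed — and tested — on WC-only stems.

## Known limitations

- The folder ignores loop penalties and multiloop costs; use the
  RNAfold import for thermodynamic accuracy.
- Ungapped duplexes only; bulged target sites are not found.
- Classification is exact-substring only (no seed-indexed alignment);
  intended for transcript/CDS-scale references, not genome-scale
  scanning performance.
- Two-library DE without replicates inherits the Audic–Claverie
  assumption of Poisson sampling around a shared rate; biological
  variance is not modeled.
- Degradome mapping is sense-strand, exact and unspliced.
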
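"""Tag classification against reference sets and known-miRNA calling.

Tags are assigned to sequence classes (rRNA, tRNA, snRNA, snoRNA, repeat,
exon, intron) by ordered exact substring matching: the first reference
class in priority order containing the tag (forward or reverse
complement) wins, so classification is a partition. Tags surviving the
non-coding filters are compared with a miRBase-style database:

* ``precursor_exact`` -- the tag is an exact substring of a same-species
  precursor;
* ``barley_overlap16`` -- an ungapped overlap of >= 16 positions with a
  same-species mature, mismatch-free inside the overlap (budget
  configurable);
* ``cross_species_2mm`` -- an alignment to any other plant mature or
  precursor with at most 2 pooled mismatches-or-gaps, accepted only when
  a fold-back precursor is verifiable at the tag's own genomic locus.

Mature miRNAs are stranded, so reverse complements count only for the
reference-class filter, never for miRNA calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .novel_hairpin import has_hairpin
from .sio import Annotation, TagRecord, normalize, revcomp

DEFAULT_CLASS_ORDER = [Annotation.RRNA, Annotation.TRNA, Annotation.SNRNA,
                       Annotation.SNORNA, Annotation.REPEAT,
                       Annotation.EXON, Annotation.INTRON]


@dataclass
class ReferenceSet:
    """One reference class with its sequences, in priority order of use."""

    label: Annotation
    sequences: list[tuple[str, str]]
    _blob: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.label = Annotation(self.label)
        self.sequences = [(i, normalize(s)) for i, s in self.sequences]
        # One separator-joined text so membership is a single scan.
        self._blob = "#" + "#".join(s for _, s in self.sequences) + "#"

    def contains(self, seq: str) -> bool:
        return seq in self._blob or revcomp(seq) in self._blob


@dataclass
class MirbaseDB:
    """Mature + precursor sequences with miRBase-style species prefixes."""

    matures: list[tuple[str, str]]
    precursors: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.matures = [(i, normalize(s)) for i, s in self.matures]
        self.precursors = [(i, normalize(s)) for i, s in self.precursors]

    @staticmethod
    def _species(name: str) -> str:
        return name.split("-")[0].lower()

    def same_species(self, species: str):
        sp = species.lower()
        return ([(i, s) for i, s in self.matures
                 if self._species(i) == sp],
                [(i, s) for i, s in self.precursors
                 if self._species(i) == sp])

    def other_species(self, species: str):
        sp = species.lower()
        return ([(i, s) for i, s in self.matures
                 if self._species(i) != sp],
                [(i, s) for i, s in self.precursors
                 if self._species(i) != sp])


@dataclass
class KnownCall:
    tag: str
    mirna_id: str
    mode: str            # precursor_exact | barley_overlap16 | cross_species_2mm
    mismatches: float = 0.0


def classify_tag(tag, reference_sets: Sequence[ReferenceSet]) -> Annotation:
    """First-match classification in the given priority order.

    A tag matches a class when it is an exact substring (forward or
    reverse complement -- tags are strandless) of any sequence in the
    class. Unmatched tags stay unassigned.
    """
    seq = tag.sequence if isinstance(tag, TagRecord) else normalize(tag)
    for ref in reference_sets:
        if ref.contains(seq):
            if isinstance(tag, TagRecord):
                tag.annotation = ref.label
            return ref.label
    return Annotation.UNASSIGNED


def best_overlap(tag: str, mature: str,
                 max_mismatches: int = 0) -> tuple[int, int]:
    """Longest ungapped aligned run with at most ``max_mismatches``.

    Over every relative offset of the two sequences, finds the longest
    contiguous stretch of aligned positions containing no more than
    ``max_mismatches`` mismatches; returns (run_length, mismatches used
    in that run). A tag sharing a clean 16-nt block with a mature thus
    scores (16, 0) even when its remainder diverges.
    """
    best = (0, 0)
    for shift in range(-(len(mature) - 1), len(tag)):
        lo = max(0, shift)
        hi = min(len(tag), shift + len(mature))
        if hi <= lo:
            continue
        matches = [tag[i] == mature[i - shift] for i in range(lo, hi)]
        left = 0
        mism = 0
        for right in range(len(matches)):
            mism += not matches[right]
            while mism > max_mismatches:
                mism -= not matches[left]
                left += 1
            run = right - left + 1
            if run > best[0] or (run == best[0] and mism < best[1]):
                best = (run, mism)
    return best


def _edit_distance(a: str, b: str, k: int, mode: str) -> int:
    res = edlib.align(a, b, mode=mode, task="distance", k=k)
    return res["editDistance"]


def call_known_mirna(tag, db: MirbaseDB, species: str = "hvu",
                     min_overlap: int = 16, overlap_mismatches: int = 0,
                     cross_budget: int = 2, genome=None,
                     ) -> KnownCall | None:
    """Identify a tag as a known miRNA, or return None.

    Rule precedence: same-species precursor substring, then the
    >= ``min_overlap`` nt ungapped overlap with a same-species mature
    (at most ``overlap_mismatches`` mismatches inside the overlap), then
    the cross-species rule (<= ``cross_budget`` pooled mismatches/gaps
    against any other-species mature or precursor, requiring a
    verifiable hairpin at the tag's locus in ``genome``; skipped when no
    genome is supplied).
    """
    seq = tag.sequence if isinstance(tag, TagRecord) else normalize(tag)
    same_mat, same_pre = db.same_species(species)
    for name, pre in same_pre:
        if seq in pre:
            return KnownCall(seq, name, "precursor_exact", 0.0)
    for name, mat in same_mat:
        overlap, mism = best_overlap(seq, mat, overlap_mismatches)
        if overlap >= min_overlap and mism <= overlap_mismatches:
            return KnownCall(seq, name, "barley_overlap16", float(mism))
    if genome is None:
        return None
    other_mat, other_pre = db.other_species(species)
    best: tuple[int, str] | None = None
    for name, mat in other_mat:
        d = _edit_distance(seq, mat, cross_budget, "NW")
        if d >= 0 and (best is None or d < best[0]):
            best = (d, name)
    for name, pre in other_pre:
        d = _edit_distance(seq, pre, cross_budget, "HW")
        if d >= 0 and (best is None or d < best[0]):
            best = (d, name)
    if best is not None and has_hairpin(seq, genome):
        return KnownCall(seq, best[1], "cross_species_2mm", float(best[0]))
    return None


def annotate_tags(tags: Sequence[TagRecord],
                  reference_sets: Sequence[ReferenceSet],
                  db: MirbaseDB | None = None, species: str = "hvu",
                  genome=None, **call_kwargs,
                  ) -> dict[str, KnownCall]:
    """Classify every tag in place; return known-miRNA calls by sequence.

    Tags matching a non-coding/genic reference class keep that
    annotation; remaining tags are tested against the miRBase-style
    database and, when called, annotated as known miRNAs.
    """
    calls: dict[str, KnownCall] = {}
    for tag in tags:
        label = classify_tag(tag, reference_sets)
        if label in (Annotation.RRNA, Annotation.TRNA, Annotation.SNRNA,
                     Annotation.SNORNA, Annotation.REPEAT):
            continue
        if db is not None:
            call = call_known_mirna(tag, db, species, genome=genome,
                                    **call_kwargs)
            if call is not None:
                tag.annotation = Annotation.KNOWN_MIRNA
                calls[tag.sequence] = call
    return calls
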
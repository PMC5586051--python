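"""Readers/writers and the canonical in-memory data model.

All sequences are stored upper-case in the DNA alphabet (U is normalized
to T on input); conversion back to RNA happens only at display/energy
boundaries. All coordinates exposed by this package are 1-based inclusive.
"""

from __future__ import annotations

import gzip
import io
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (U treated as T)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Upper-case and convert U to T (internal canonical alphabet)."""
    return seq.upper().replace("U", "T")


class Annotation(str, Enum):
    """Sequence class assigned to a small-RNA tag."""

    UNASSIGNED = "unassigned"
    RRNA = "rRNA"
    TRNA = "tRNA"
    SNRNA = "snRNA"
    SNORNA = "snoRNA"
    REPEAT = "repeat"
    EXON = "exon"
    INTRON = "intron"
    KNOWN_MIRNA = "known_miRNA"
    NOVEL_MIRNA = "novel_miRNA"


@dataclass
class TagRecord:
    """A distinct small-RNA sequence with per-library read counts.

    The unit of all quantification downstream: identical reads are
    collapsed into one record whose counts map library id -> reads.
    """

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation: Annotation = Annotation.UNASSIGNED

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if not self.sequence:
            raise ValueError("TagRecord sequence must be non-empty")
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError(f"invalid bases in {self.sequence!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("read counts must be non-negative")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SiteReport:
    """One predicted (and possibly degradome-validated) binding site."""

    mirna_id: str
    transcript_id: str
    start: int                    # 1-based inclusive on the transcript/CDS
    end: int
    cut: int                      # predicted slicing coordinate (end - 9)
    mismatch_total: float
    energy_ratio: float
    validated: bool = False
    category: int | None = None
    peak_position: int | None = None
    secondary_peaks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("site start must be <= end")
        if not self.start <= self.cut <= self.end:
            raise ValueError("cut coordinate must lie within the site")


class CountMatrix:
    """Tag/miRNA counts per library plus library totals (clean reads).

    ``library_totals[l]`` is the total clean-read count of library ``l``
    and must be at least the column sum (tags may be dropped by
    annotation filters without shrinking the normalization denominator).
    """

    def __init__(self, counts: pd.DataFrame,
                 library_totals: Mapping[str, int] | None = None):
        counts = counts.fillna(0).astype(int)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if library_totals is None:
            library_totals = counts.sum(axis=0).to_dict()
        for lib in counts.columns:
            if library_totals[lib] < counts[lib].sum():
                raise ValueError(
                    f"library_totals[{lib!r}] below the column sum")
        self.counts = counts
        self.library_totals = dict(library_totals)

    @classmethod
    def from_tags(cls, tags: Sequence[TagRecord],
                  library_totals: Mapping[str, int] | None = None,
                  libraries: Sequence[str] | None = None) -> "CountMatrix":
        if libraries is None:
            libraries = sorted({lib for t in tags for lib in t.counts})
        rows = {t.sequence: {lib: t.counts.get(lib, 0) for lib in libraries}
                for t in tags}
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=list(libraries)).fillna(0)
        return cls(df.astype(int), library_totals)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        with _open_write(path) as fh:
            totals = "\t".join(str(self.library_totals[l])
                               for l in self.counts.columns)
            fh.write(f"#library_totals\t{totals}\n")
            self.counts.to_csv(fh, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        with _open_read(path) as fh:
            first = fh.readline()
            totals = None
            if first.startswith("#library_totals"):
                vals = [int(x) for x in first.rstrip("\n").split("\t")[1:]]
                body = fh.read()
            else:
                body = first + fh.read()
                vals = None
            df = pd.read_csv(io.StringIO(body), sep="\t", index_col=0)
            if vals is not None:
                totals = dict(zip(df.columns, vals))
        return cls(df, totals)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _open_read(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_write(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into [(id, sequence)]; upper-cased, U->T normalized.

    Duplicate ids are suffix-deduplicated (``id.2``, ``id.3`` ...) with a
    warning. Malformed records raise ``ValueError`` naming the line.
    """
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    with _open_read(path) as fh:
        name = None
        chunks: list[str] = []
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, normalize("".join(chunks))))
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError(f"{path}: empty FASTA header "
                                     f"at line {lineno}")
                if name in seen:
                    seen[name] += 1
                    new = f"{name}.{seen[name]}"
                    warnings.warn(f"duplicate FASTA id {name!r} renamed "
                                  f"to {new!r}")
                    name = new
                else:
                    seen[name] = 1
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before any header "
                                     f"at line {lineno}")
                chunks.append(line.strip())
        if name is not None:
            records.append((name, normalize("".join(chunks))))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with _open_write(path) as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ into [(id, sequence, quality)] via Bio.SeqIO."""
    out = []
    with _open_read(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33)
                           for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, normalize(str(rec.seq)), qual))
    return out


# ---------------------------------------------------------------------------
# Collapsed FASTA (the standard ``>id_xCOUNT`` dialect)
# ---------------------------------------------------------------------------

def read_collapsed_fasta(path: str | Path,
                         library: str = "lib") -> list[TagRecord]:
    """Read collapsed reads; duplicate sequences merge by summing counts."""
    merged: "OrderedDict[str, int]" = OrderedDict()
    for name, seq in read_fasta(path):
        head, sep, count = name.rpartition("_x")
        if not sep or not count.isdigit() or int(count) < 1:
            raise ValueError(
                f"{path}: header {name!r} lacks an `_x<count>` suffix")
        merged[seq] = merged.get(seq, 0) + int(count)
    return [TagRecord(seq, {library: n}) for seq, n in merged.items()]


def write_collapsed_fasta(tags: Sequence[TagRecord], path: str | Path,
                          library: str | None = None,
                          prefix: str = "t") -> None:
    """Write tags as ``>t<i>_x<count>``; counts for one library or totals."""
    with _open_write(path) as fh:
        i = 0
        for tag in tags:
            n = tag.counts.get(library, 0) if library else tag.total_count
            if n <= 0:
                continue
            i += 1
            fh.write(f">{prefix}{i}_x{n}\n{tag.sequence}\n")


# ---------------------------------------------------------------------------
# Degradome tags, term tables, site reports
# ---------------------------------------------------------------------------

def read_degradome_tags(path: str | Path) -> list[tuple[str, int]]:
    """Read degradome 5'-tags from TSV (sequence<TAB>count) or FASTA.

    FASTA input uses collapsed headers when present, otherwise count 1.
    """
    path = Path(path)
    with _open_read(path) as fh:
        first = fh.read(1)
    if first == ">":
        out = []
        for name, seq in read_fasta(path):
            head, sep, count = name.rpartition("_x")
            out.append((seq, int(count) if sep and count.isdigit() else 1))
        return out
    tags = []
    with _open_read(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].isdigit():
                raise ValueError(f"{path}: bad degradome line {lineno}")
            tags.append((normalize(parts[0]), int(parts[1])))
    return tags


def read_term_table(path: str | Path) -> dict[str, set[str]]:
    """Read a gene<TAB>term table into gene -> set of terms."""
    table: dict[str, set[str]] = {}
    with _open_read(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: bad term line {lineno}")
            table.setdefault(parts[0], set()).add(parts[1])
    return table


SITE_REPORT_COLUMNS = [
    "miRNA", "transcript", "start", "end", "cut", "mismatches",
    "energy_ratio", "validated", "category", "peak", "secondary_peaks",
]


def write_site_report(sites: Sequence[SiteReport], path: str | Path) -> None:
    """Write a TSV site report, rows sorted by (transcript id, start)."""
    with _open_write(path) as fh:
        fh.write("\t".join(SITE_REPORT_COLUMNS) + "\n")
        for s in sorted(sites, key=lambda s: (s.transcript_id, s.start,
                                              s.end, s.mirna_id)):
            fh.write("\t".join([
                s.mirna_id, s.transcript_id, str(s.start), str(s.end),
                str(s.cut), f"{s.mismatch_total:g}",
                f"{s.energy_ratio:.4f}",
                "yes" if s.validated else "no",
                "" if s.category is None else str(s.category),
                "" if s.peak_position is None else str(s.peak_position),
                ",".join(map(str, s.secondary_peaks)),
            ]) + "\n")
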
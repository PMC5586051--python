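"""Raw-read cleaning and library-level summaries.

Mirrors the data-cleaning stage of a small-RNA sequencing run: drop
low-quality reads, discard 5' adaptor contaminants, trim 3' adapters,
and keep inserts of 18-30 nt. Surviving reads are collapsed immediately
into :class:`~srnapipe.sio.TagRecord` objects.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

from .sio import TagRecord, normalize


@dataclass
class CleaningConfig:
    min_len: int = 18
    max_len: int = 30
    adapter_5p: str = ""
    adapter_3p: str = ""
    max_n_fraction: float = 0.0
    min_quality: int = 20          # reads with any base below are dropped
    adapter3_seed: int = 8         # seed length for 3' adapter detection

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        self.adapter_5p = normalize(self.adapter_5p) if self.adapter_5p else ""
        self.adapter_3p = normalize(self.adapter_3p) if self.adapter_3p else ""


@dataclass
class CleaningStats:
    """Per-rule removal counters; removed + kept reads = input reads."""

    input_reads: int = 0
    low_quality: int = 0
    adapter5_contaminant: int = 0
    too_short: int = 0
    too_long: int = 0
    n_excess: int = 0
    kept_reads: int = 0
    trimmed_3p: int = 0            # informational, not a removal

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in (
            "input_reads", "low_quality", "adapter5_contaminant",
            "too_short", "too_long", "n_excess", "kept_reads",
            "trimmed_3p")}


def _iter_reads(raw_reads):
    """Yield (sequence, quality-or-None, count) from heterogeneous input."""
    for item in raw_reads:
        if isinstance(item, TagRecord):
            yield item.sequence, None, item.total_count
        elif isinstance(item, str):
            yield item, None, 1
        elif len(item) == 3:
            yield item[1], item[2], 1
        else:
            yield item[1], None, 1


def clean_reads(raw_reads, config: CleaningConfig | None = None,
                library: str = "lib") -> tuple[list[TagRecord], CleaningStats]:
    """Clean raw reads and collapse survivors into TagRecords.

    Accepts plain sequences, (id, seq) pairs, (id, seq, qual) triples or
    already-collapsed TagRecords (counts are preserved). The filter order
    is quality -> 5' adaptor -> 3' adapter trim -> N content -> length;
    stats record the reads removed by each rule so that
    removed + kept = input (conservation).
    """
    cfg = config or CleaningConfig()
    stats = CleaningStats()
    merged: "OrderedDict[str, int]" = OrderedDict()
    for seq, qual, count in _iter_reads(raw_reads):
        seq = normalize(seq)
        stats.input_reads += count
        if qual is not None and any(ord(q) - 33 < cfg.min_quality
                                    for q in qual):
            stats.low_quality += count
            continue
        if cfg.adapter_5p and seq.startswith(cfg.adapter_5p):
            stats.adapter5_contaminant += count
            continue
        if cfg.adapter_3p:
            seed = cfg.adapter_3p[:cfg.adapter3_seed]
            pos = seq.find(seed)
            if pos >= 0:
                seq = seq[:pos]
                stats.trimmed_3p += count
        if len(seq) < cfg.min_len:
            stats.too_short += count
            continue
        if len(seq) > cfg.max_len:
            stats.too_long += count
            continue
        if len(seq) and seq.count("N") / len(seq) > cfg.max_n_fraction:
            stats.n_excess += count
            continue
        stats.kept_reads += count
        merged[seq] = merged.get(seq, 0) + count
    tags = [TagRecord(s, {library: n}) for s, n in merged.items()]
    return tags, stats


def length_distribution(tags) -> dict[int, tuple[int, float]]:
    """Read-count weighted length distribution: length -> (count, fraction).

    Fractions are computed on read counts, not distinct sequences, and
    sum to 1 (empty input gives an empty map).
    """
    counts: dict[int, int] = {}
    for tag in tags:
        counts[len(tag.sequence)] = (counts.get(len(tag.sequence), 0)
                                     + tag.total_count)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {ln: (n, n / total) for ln, n in sorted(counts.items())}
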
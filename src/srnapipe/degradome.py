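"""Degradome (PARE) tag mapping and cleavage-site validation.

Degradome 5' tags are the first nucleotides of uncapped 3' cleavage
fragments; a pile-up of tag 5' ends at the position opposite miRNA
positions 10-11 is the sequencing signature of slicing. Tags are mapped
to transcripts by exact sense-strand matching, summed into per-position
profiles (T-plots), and predicted target sites are validated when a
sufficiently abundant peak falls within a small window of the expected
cut coordinate. Peaks carry CleaveLand-style abundance categories 0-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sio import SiteReport, TagRecord, normalize
from .target_duplex import TargetSite, site_to_report

MIN_TAG_LEN = 15


@dataclass
class DegradomeProfile:
    """Per-position summed 5'-tag counts along one transcript (1-based)."""

    transcript_id: str
    counts: np.ndarray          # length = transcript length; index 0 = pos 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count_at(self, pos: int) -> int:
        if 1 <= pos <= len(self.counts):
            return int(self.counts[pos - 1])
        return 0


@dataclass
class DegradomePeak:
    position: int
    count: int
    category: int


def _tag_iter(tags) -> Iterable[tuple[str, int]]:
    for t in tags:
        if isinstance(t, TagRecord):
            yield t.sequence, t.total_count
        else:
            yield normalize(t[0]), int(t[1])


def map_tags(tags, transcripts) -> dict[str, DegradomeProfile]:
    """Map degradome tags to transcripts by exact sense-strand match.

    A tag of count c increments position p of transcript t by c for every
    exact occurrence of the tag starting at p (1-based); multi-mapping
    tags increment every locus. Tags shorter than 15 nt are ignored.
    """
    if isinstance(transcripts, dict):
        transcripts = transcripts.items()
    transcripts = [(tid, normalize(seq)) for tid, seq in transcripts]
    profiles = {tid: DegradomeProfile(tid, np.zeros(len(seq), dtype=np.int64))
                for tid, seq in transcripts}
    for seq, count in _tag_iter(tags):
        if len(seq) < MIN_TAG_LEN:
            continue
        for tid, tseq in transcripts:
            start = 0
            while True:
                p = tseq.find(seq, start)
                if p < 0:
                    break
                profiles[tid].counts[p] += count
                start = p + 1
    return profiles


def validate_site(site: TargetSite, profile: DegradomeProfile,
                  window: int = 1, min_reads: int = 2,
                  ) -> tuple[bool, DegradomePeak | None]:
    """Validate a predicted site against the transcript's T-plot.

    Let c be the maximum tag count within ``expected_cut +/- window``.
    The site is validated when c >= ``min_reads``. The peak category
    follows the degradome de-facto standard: 0 when c is the unique
    transcript-wide maximum, 1 when it ties the maximum, 2 when it
    exceeds the median of nonzero positions, 3 when c > 1 otherwise,
    4 when c == 1. The reported position is the arg-max inside the
    window (ties resolve to the position nearest the expected cut, then
    the smaller coordinate).
    """
    cut = site.expected_cut
    lo = max(1, cut - window)
    hi = min(len(profile.counts), cut + window)
    if lo > hi:
        return False, None
    segment = profile.counts[lo - 1:hi]
    c = int(segment.max()) if len(segment) else 0
    if c == 0:
        return False, None
    cands = [lo + i for i in range(len(segment)) if segment[i] == c]
    peak_pos = min(cands, key=lambda p: (abs(p - cut), p))
    tmax = int(profile.counts.max())
    nonzero = profile.counts[profile.counts > 0]
    median = float(np.median(nonzero)) if len(nonzero) else 0.0
    if c == tmax and int((profile.counts == tmax).sum()) == 1:
        category = 0
    elif c == tmax:
        category = 1
    elif c > median:
        category = 2
    elif c > 1:
        category = 3
    else:
        category = 4
    return c >= min_reads, DegradomePeak(peak_pos, c, category)


def report_validated_pairs(sites: Sequence[TargetSite],
                           profiles: Mapping[str, DegradomeProfile],
                           window: int = 1, min_reads: int = 2,
                           ) -> list[SiteReport]:
    """Site-report rows for the degradome-validated sites only.

    Off-site positions whose tag abundance is >= the on-site peak are
    listed as secondary peaks (as in reports where a stronger distal
    pile-up accompanies the validated cut site).
    """
    rows: list[SiteReport] = []
    for site in sites:
        profile = profiles.get(site.transcript_id)
        if profile is None:
            continue
        ok, peak = validate_site(site, profile, window, min_reads)
        if not ok or peak is None:
            continue
        row = site_to_report(site)
        row.validated = True
        row.category = peak.category
        row.peak_position = peak.position
        cut = site.expected_cut
        off = [int(p) + 1 for p in np.nonzero(
            profile.counts >= peak.count)[0]
            if abs(int(p) + 1 - cut) > window]
        row.secondary_peaks = tuple(sorted(off))
        rows.append(row)
    rows.sort(key=lambda r: (r.transcript_id, r.start))
    return rows
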
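"""miRNA/target duplex scoring under the six plant complementarity rules.

A candidate site is the antiparallel, ungapped pairing of a miRNA with a
transcript window of equal length. Positions are numbered from the miRNA
5' end; position i of the miRNA faces site position L - i + 1. G.U wobbles
count 0.5 toward mismatch totals but are treated as pairs (not mismatches)
for the adjacency and position-specific rules, following Allen-style plant
target scoring (configurable).

The rules:
  1. total mismatches <= 4 (G.U = 0.5);
  2. no more than two consecutive mismatches;
  3. no adjacent mismatches within miRNA positions 2-12;
  4. no mismatch at positions 10-11 (the slicing positions);
  5. <= 2.5 mismatches within positions 1-12;
  6. duplex MFE >= 75% of the MFE of the miRNA bound to its perfect
     complement (energy ratio >= 0.75), both computed with the same
     embedded nearest-neighbor stack table.

The expected slicing coordinate of a site [start, end] on the transcript
is end - 9: the bond opposite miRNA positions 10-11.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._thermo import BASE_CODE, PAIR_TABLE, STACK_ENERGY
from .sio import SiteReport, normalize, revcomp

WC = "WC"
GU = "GU"
MISMATCH = "mismatch"

CUT_OFFSET = 9  # expected cut coordinate = site end - CUT_OFFSET


@dataclass
class RulesConfig:
    max_mismatch: float = 4.0
    max_consecutive: int = 2          # rule 2: runs longer than this fail
    adjacent_window: tuple[int, int] = (2, 12)
    seed_positions: tuple[int, int] = (10, 11)
    max_5p_mismatch: float = 2.5
    fivep_window: tuple[int, int] = (1, 12)
    min_energy_ratio: float = 0.75
    gu_is_mismatch: bool = False      # count G.U as a full mismatch in R2-R4


@dataclass
class DuplexAlignment:
    """Pairing of a miRNA (5'->3') with a same-length target site."""

    mirna: str
    site: str                          # 5'->3' on the transcript
    states: tuple[str, ...] = ()       # per miRNA position 1..L
    mismatch_total: float = 0.0
    mismatch_5p_1_12: float = 0.0
    energy: float = 0.0
    perfect_energy: float = 0.0
    energy_ratio: float = 0.0


@dataclass
class TargetSite:
    transcript_id: str
    start: int                         # 1-based inclusive
    end: int
    duplex: DuplexAlignment
    mirna_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end - self.start + 1 != len(
                self.duplex.mirna):
            raise ValueError("site span must equal the miRNA length")

    @property
    def expected_cut(self) -> int:
        return self.end - CUT_OFFSET


def _pair_state(m_base: str, t_base: str) -> str:
    """Pair state of a miRNA base against the target base it faces."""
    p = PAIR_TABLE[BASE_CODE[m_base], BASE_CODE[t_base]]
    if p < 0:
        return MISMATCH
    return GU if m_base + t_base in ("GT", "TG") else WC


def pair_states(mirna: str, site: str,
                fivep_window: tuple[int, int] = (1, 12)) -> DuplexAlignment:
    """Compute per-position pair states of the antiparallel duplex.

    ``site`` is the transcript window read 5'->3'; miRNA position i faces
    site position L - i + 1. Energies are filled in as well.
    """
    mirna, site = normalize(mirna), normalize(site)
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must have equal lengths")
    L = len(mirna)
    states = tuple(_pair_state(mirna[i], site[L - 1 - i]) for i in range(L))
    total = sum(1.0 if s == MISMATCH else 0.5 if s == GU else 0.0
                for s in states)
    lo, hi = fivep_window
    total_5p = sum(1.0 if s == MISMATCH else 0.5 if s == GU else 0.0
                   for s in states[lo - 1:hi])
    dup = DuplexAlignment(mirna, site, states, total, total_5p)
    dup.energy = duplex_energy(dup)
    perfect = pair_states_energy_only(mirna, revcomp(mirna))
    dup.perfect_energy = perfect
    dup.energy_ratio = (dup.energy / perfect) if perfect < 0 else (
        1.0 if dup.energy == perfect else 0.0)
    return dup


def pair_states_energy_only(mirna: str, site: str) -> float:
    """Duplex energy of mirna vs site without building a full alignment."""
    L = len(mirna)
    states = [_pair_state(mirna[i], site[L - 1 - i]) for i in range(L)]
    return _stack_sum(mirna, site, states)


def _stack_sum(mirna: str, site: str, states: Sequence[str]) -> float:
    """Sum nearest-neighbor stack energies over runs of paired positions.

    Positions i and i+1 (miRNA numbering) both paired contribute the
    stack of pair(i) over pair(i+1); mismatches contribute nothing and
    break stacks. The result is <= 0 by construction (the single
    destabilizing G.U-on-G.U motif is clipped at zero so that degrading
    a duplex can never lower its energy).
    """
    L = len(mirna)
    total = 0.0
    for i in range(L - 1):
        if states[i] == MISMATCH or states[i + 1] == MISMATCH:
            continue
        p1 = PAIR_TABLE[BASE_CODE[mirna[i]], BASE_CODE[site[L - 1 - i]]]
        p2 = PAIR_TABLE[BASE_CODE[mirna[i + 1]],
                        BASE_CODE[site[L - 2 - i]]]
        total += min(0.0, STACK_ENERGY[p1, p2])
    return round(total, 4)


def duplex_energy(duplex: DuplexAlignment) -> float:
    """Free energy (kcal/mol, <= 0) of a duplex from its pair states."""
    return _stack_sum(duplex.mirna, duplex.site, duplex.states)


def apply_rules(duplex: DuplexAlignment,
                config: RulesConfig | None = None,
                ) -> tuple[bool, set[int]]:
    """Evaluate the six rules; returns (pass, set of failed rule numbers)."""
    cfg = config or RulesConfig()
    failed: set[int] = set()
    if cfg.gu_is_mismatch:
        hard = [s != WC for s in duplex.states]
    else:
        hard = [s == MISMATCH for s in duplex.states]
    if duplex.mismatch_total > cfg.max_mismatch:
        failed.add(1)
    run = best_run = 0
    for h in hard:
        run = run + 1 if h else 0
        best_run = max(best_run, run)
    if best_run > cfg.max_consecutive:
        failed.add(2)
    lo, hi = cfg.adjacent_window
    if any(hard[i - 1] and hard[i] for i in range(lo, hi)):
        failed.add(3)
    if any(hard[p - 1] for p in cfg.seed_positions
           if p <= len(duplex.states)):
        failed.add(4)
    if duplex.mismatch_5p_1_12 > cfg.max_5p_mismatch:
        failed.add(5)
    if duplex.energy_ratio < cfg.min_energy_ratio:
        failed.add(6)
    return not failed, failed


def scan_transcript(mirna: str, transcript: str,
                    rules_config: RulesConfig | None = None,
                    transcript_id: str = "", mirna_id: str = "",
                    ) -> list[TargetSite]:
    """Evaluate every window of the transcript against the six rules.

    Returns the passing sites sorted by (mismatch_total, -energy_ratio,
    start). All overlapping passing windows are reported; degradome
    validation disambiguates downstream.
    """
    cfg = rules_config or RulesConfig()
    mirna, transcript = normalize(mirna), normalize(transcript)
    L = len(mirna)
    if len(transcript) < L:
        return []
    sites = []
    perfect = pair_states_energy_only(mirna, revcomp(mirna))
    for start0 in range(len(transcript) - L + 1):
        window = transcript[start0:start0 + L]
        states = tuple(_pair_state(mirna[i], window[L - 1 - i])
                       for i in range(L))
        total = sum(1.0 if s == MISMATCH else 0.5 if s == GU else 0.0
                    for s in states)
        if total > cfg.max_mismatch:       # cheap pre-filter (rule 1)
            continue
        lo, hi = cfg.fivep_window
        dup = DuplexAlignment(
            mirna, window, states, total,
            sum(1.0 if s == MISMATCH else 0.5 if s == GU else 0.0
                for s in states[lo - 1:hi]))
        dup.energy = _stack_sum(mirna, window, states)
        dup.perfect_energy = perfect
        dup.energy_ratio = (dup.energy / perfect) if perfect < 0 else 0.0
        ok, _ = apply_rules(dup, cfg)
        if ok:
            sites.append(TargetSite(transcript_id or "transcript",
                                    start0 + 1, start0 + L, dup,
                                    mirna_id or "miRNA"))
    sites.sort(key=lambda s: (s.duplex.mismatch_total,
                              -s.duplex.energy_ratio, s.start))
    return sites


def site_to_report(site: TargetSite) -> SiteReport:
    return SiteReport(
        mirna_id=site.mirna_id, transcript_id=site.transcript_id,
        start=site.start, end=site.end, cut=site.expected_cut,
        mismatch_total=site.duplex.mismatch_total,
        energy_ratio=site.duplex.energy_ratio)
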
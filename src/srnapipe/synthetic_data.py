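"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a plant embryo
small-RNA experiment: libraries dominated by 24-nt reads with a 21-nt
secondary population, planted mature miRNAs sitting on fold-back
precursors in an otherwise random genome, dinucleotide-shuffled decoy
hairpins, transcripts carrying binding sites that satisfy (or
deliberately violate, with the violated rule recorded) the six duplex
rules, and degradome libraries whose 5' ends pile up at the position
opposite miRNA positions 10-11 (site end - 9) over per-position Poisson
noise.

All generators are pure functions of (parameters, seed): the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .sio import TagRecord, normalize, revcomp
from .target_duplex import CUT_OFFSET

BASES = "ACGT"

#: Default read-length mix: 24-nt dominant, 21-nt secondary population.
DEFAULT_LENGTH_MIX = {
    18: 0.02, 19: 0.03, 20: 0.05, 21: 0.20, 22: 0.07, 23: 0.08,
    24: 0.40, 25: 0.06, 26: 0.03, 27: 0.02, 28: 0.02, 29: 0.01, 30: 0.01,
}

MATURE_LEN = 21
STEM_EXT5 = 6          # stem nucleotides flanking the mature on its arm
STEM_EXT3 = 5
LOOP_LEN = 8
HAIRPIN_SPACING = 620  # background between planted blocks (> excision flank)


@dataclass
class PlantedMirna:
    mirna_id: str
    sequence: str
    chrom: str
    start: int          # 1-based genome coords of the mature
    end: int
    arm: str


@dataclass
class PlantedDecoy:
    decoy_id: str
    sequence: str       # the tag slice taken from the shuffled block
    chrom: str
    start: int
    end: int


@dataclass
class PlantedSite:
    mirna_id: str
    transcript_id: str
    start: int
    end: int
    cut: int
    compliant: bool
    violated_rule: int | None = None


@dataclass
class SimulationTruth:
    seed: int
    mirnas: list[PlantedMirna] = field(default_factory=list)
    decoys: list[PlantedDecoy] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        raw = json.loads(Path(path).read_text())
        return cls(seed=raw["seed"],
                   mirnas=[PlantedMirna(**m) for m in raw["mirnas"]],
                   decoys=[PlantedDecoy(**d) for d in raw["decoys"]],
                   sites=[PlantedSite(**s) for s in raw["sites"]])


def _random_seq(rng: np.random.Generator, n: int,
                p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=list(p)))


def _wobbled_rc(top: str, rng: np.random.Generator, n_wobble: int) -> str:
    """Reverse complement of ``top`` with G.U wobbles at n_wobble sites.

    Wobbles keep the duplex paired (G.U is a pair) while breaking perfect
    Watson-Crick symmetry, as in real precursor stems.
    """
    rc = list(revcomp(top))
    eligible = [i for i in range(len(rc)) if top[len(top) - 1 - i] in "GT"]
    for i in rng.permutation(len(eligible))[:n_wobble]:
        pos = eligible[int(i)]
        rc[pos] = "T" if top[len(top) - 1 - pos] == "G" else "G"
    return "".join(rc)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator,
                          max_tries: int = 200) -> str:
    """Shuffle preserving dinucleotide counts (random Eulerian walk)."""
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for _ in range(max_tries):
        pool = {a: [bs[i] for i in rng.permutation(len(bs))]
                for a, bs in edges.items()}
        walk = [seq[0]]
        node = seq[0]
        ok = True
        for _step in range(len(seq) - 1):
            nxt = pool.get(node)
            if not nxt:
                ok = False
                break
            node = nxt.pop()
            walk.append(node)
        if ok:
            return "".join(walk)
    return "".join(seq[i] for i in rng.permutation(len(seq)))  # fallback


def _build_hairpin(rng: np.random.Generator, arm: str,
                   ) -> tuple[str, str, int]:
    """Return (precursor, mature, mature offset within the precursor)."""
    mature = _random_seq(rng, MATURE_LEN, p=(0.22, 0.28, 0.28, 0.22))
    block = (_random_seq(rng, STEM_EXT5) + mature
             + _random_seq(rng, STEM_EXT3))
    loop = _random_seq(rng, LOOP_LEN)
    partner = _wobbled_rc(block, rng, n_wobble=3)
    if arm == "5p":
        precursor = block + loop + partner
        offset = STEM_EXT5
    else:
        precursor = partner + loop + block
        offset = len(partner) + LOOP_LEN + STEM_EXT5
    return precursor, mature, offset


def make_genome(n_hairpins: int = 50, n_decoys: int = 50, seed: int = 0,
                chrom: str = "chr1",
                ) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """A synthetic chromosome with planted hairpins and shuffled decoys.

    Hairpins are stem-loop precursors (~32-bp stems, >= 80% Watson-Crick
    with a few G.U wobbles, 8-nt loop) spaced by random background wider
    than the excision flank. Decoys are dinucleotide-shuffled precursors;
    the decoy tag is the 21-mer occupying the mature's positional slice
    of the shuffled block.
    """
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    blocks: list[str] = [_random_seq(rng, HAIRPIN_SPACING)]
    pos = len(blocks[0])
    kinds = ["mir"] * n_hairpins + ["decoy"] * n_decoys
    kinds = [kinds[int(i)] for i in rng.permutation(len(kinds))]
    i_mir = i_dec = 0
    for kind in kinds:
        arm = "5p" if rng.random() < 0.5 else "3p"
        precursor, mature, offset = _build_hairpin(rng, arm)
        if kind == "mir":
            i_mir += 1
            start = pos + offset + 1
            truth.mirnas.append(PlantedMirna(
                f"syn-mir-{i_mir}", mature, chrom, start,
                start + MATURE_LEN - 1, arm))
            blocks.append(precursor)
        else:
            i_dec += 1
            shuffled = _dinucleotide_shuffle(precursor, rng)
            tag = shuffled[offset:offset + MATURE_LEN]
            start = pos + offset + 1
            truth.decoys.append(PlantedDecoy(
                f"syn-decoy-{i_dec}", tag, chrom, start,
                start + MATURE_LEN - 1))
            blocks.append(shuffled)
        pos += len(precursor)
        blocks.append(_random_seq(rng, HAIRPIN_SPACING))
        pos += HAIRPIN_SPACING
    return [(chrom, "".join(blocks))], truth


def make_srna_library(truth: SimulationTruth, depth: int = 50_000,
                      length_mix: dict[int, float] | None = None,
                      seed: int = 0, mirna_frac: float = 0.15,
                      decoy_frac: float = 0.05, library: str = "lib",
                      mirna_weights: dict[str, float] | None = None,
                      ) -> list[TagRecord]:
    """Draw a collapsed small-RNA library of ``depth`` reads.

    Planted matures share ``mirna_frac`` of the reads (optionally skewed
    by ``mirna_weights``; weight 0 removes a miRNA from the library),
    decoy tags share ``decoy_frac``, and the remainder are background
    fragments whose lengths follow ``length_mix`` (default: 24-nt peak,
    21-nt secondary).
    """
    rng = np.random.default_rng(seed)
    mix = length_mix or DEFAULT_LENGTH_MIX
    lengths = sorted(mix)
    probs = np.array([mix[ln] for ln in lengths], dtype=float)
    probs = probs / probs.sum()

    # Relative weights within the mature pool (weight 0 removes a miRNA);
    # matures share mirna_frac of the reads, decoys decoy_frac.
    mir_pool = [(m.sequence,
                 1.0 if mirna_weights is None
                 else mirna_weights.get(m.mirna_id, 1.0))
                for m in truth.mirnas]
    mir_pool = [(s, w) for s, w in mir_pool if w > 0]
    mir_total = sum(w for _, w in mir_pool)
    planted = ([(s, mirna_frac * w / mir_total) for s, w in mir_pool]
               if mir_total > 0 else [])
    if truth.decoys:
        planted += [(d.sequence, decoy_frac / len(truth.decoys))
                    for d in truth.decoys]

    mass = sum(w for _, w in planted)
    all_w = np.array([w for _, w in planted] + [max(0.0, 1.0 - mass)])
    all_w = all_w / all_w.sum()
    draws = rng.multinomial(depth, all_w)

    merged: dict[str, int] = {}
    for (seq, _), n in zip(planted, draws[:-1]):
        if n > 0:
            merged[seq] = merged.get(seq, 0) + int(n)
    n_bg = int(draws[-1])
    if n_bg:
        bg_lengths = rng.choice(lengths, size=n_bg, p=probs)
        for ln in bg_lengths:
            seq = _random_seq(rng, int(ln))
            merged[seq] = merged.get(seq, 0) + 1
    return [TagRecord(s, {library: n}) for s, n in merged.items()]


# -- target / degradome ------------------------------------------------------

# Degradations guaranteed to keep all six rules satisfied: at most one
# full mismatch plus one G.U, both in the 3' half away from positions
# 10-11 and never adjacent.
_COMPLIANT_CLASSES = [(), ("gu", 16), ("mm", 18), ("mm", 14, "gu", 20)]
# One violation class per rule 1-4 (each breaks exactly that rule).
_VIOLATION_CLASSES = {
    1: ("mm", 3, "mm", 6, "mm", 14, "mm", 17, "mm", 20),
    2: ("mm", 14, "mm", 15, "mm", 16),
    3: ("mm", 5, "mm", 6),
    4: ("mm", 10),
}


def _degrade_site(mirna: str, spec: tuple) -> str:
    """Build the target-side site (5'->3') applying (kind, pos) edits.

    Positions are miRNA positions (1-based from the miRNA 5' end); the
    unedited site is the exact reverse complement.
    """
    L = len(mirna)
    site = list(revcomp(mirna))
    for kind, pos in zip(spec[::2], spec[1::2]):
        m_base = mirna[pos - 1]
        idx = L - pos            # site index facing miRNA position pos
        if kind == "gu":
            # G.U requires the miRNA base be G or T; fall back to a G
            # against a U (miRNA T) or U against G.
            if m_base == "G":
                site[idx] = "T"
            elif m_base == "T":
                site[idx] = "G"
            else:               # no wobble possible: leave Watson-Crick
                continue
        else:
            wc = {"A": "T", "T": "A", "G": "C", "C": "G"}[m_base]
            bad = [b for b in BASES
                   if b != wc and (m_base, b) not in (("G", "T"), ("T", "G"))]
            site[idx] = bad[0]
    return "".join(site)


def make_targets_and_degradome(
        truth: SimulationTruth, transcripts_n: int = 40,
        n_compliant: int = 20, n_violating: int = 20,
        signal_reads: int = 50, noise_rate: float = 0.1, seed: int = 0,
        tag_len: int = 20,
        ) -> tuple[list[tuple[str, str]], list[tuple[str, int]]]:
    """Transcripts with planted binding sites plus a degradome library.

    Each planted site (compliant or rule-violating) receives
    ``signal_reads`` degradome tags whose 5' ends sit exactly at the
    planted cut (site end - 9); every other position receives
    Poisson(``noise_rate``) background tags. Planted sites are recorded
    in ``truth.sites`` with their compliance class.
    """
    rng = np.random.default_rng(seed)
    tx_len = 1500
    transcripts = [(f"tx{i + 1}", _random_seq(rng, tx_len))
                   for i in range(transcripts_n)]
    seqs = {tid: list(seq) for tid, seq in transcripts}
    if not truth.mirnas:
        raise ValueError("truth carries no planted miRNAs")

    slots_per_tx = (tx_len - 400) // 300
    slot_list = [(transcripts[i % transcripts_n][0],
                  200 + (i // transcripts_n % slots_per_tx) * 300)
                 for i in range(n_compliant + n_violating)]
    plan = ([("ok", _COMPLIANT_CLASSES[i % len(_COMPLIANT_CLASSES)], None)
             for i in range(n_compliant)]
            + [("bad", _VIOLATION_CLASSES[r], r)
               for i in range(n_violating)
               for r in [sorted(_VIOLATION_CLASSES)[i %
                                                    len(_VIOLATION_CLASSES)]]])
    for i, ((kind, spec, rule), (tid, start)) in enumerate(zip(plan,
                                                               slot_list)):
        mirna = truth.mirnas[i % len(truth.mirnas)]
        site_seq = _degrade_site(mirna.sequence, spec)
        end = start + len(site_seq) - 1
        seqs[tid][start - 1:end] = list(site_seq)
        truth.sites.append(PlantedSite(
            mirna.mirna_id, tid, start, end, end - CUT_OFFSET,
            compliant=(kind == "ok"), violated_rule=rule))
    transcripts = [(tid, "".join(seqs[tid])) for tid, _ in transcripts]

    tag_counts: dict[str, int] = {}
    by_id = dict(transcripts)
    for site in truth.sites[-len(plan):] if plan else []:
        seq = by_id[site.transcript_id]
        tag = seq[site.cut - 1:site.cut - 1 + tag_len]
        if len(tag) >= 15 and signal_reads > 0:
            tag_counts[tag] = tag_counts.get(tag, 0) + signal_reads
    if noise_rate > 0:
        for tid, seq in transcripts:
            noise = rng.poisson(noise_rate, size=len(seq) - tag_len + 1)
            for p0 in np.nonzero(noise)[0]:
                tag = seq[p0:p0 + tag_len]
                tag_counts[tag] = tag_counts.get(tag, 0) + int(noise[p0])
    return transcripts, sorted(tag_counts.items())


def make_term_table(study_genes, background_genes, seed: int = 0,
                    n_terms: int = 10, enriched_term: str = "TERM:enriched",
                    ) -> dict[str, set[str]]:
    """A gene->terms table with one term planted as enriched in the study.

    Background genes receive 1-3 random terms; study genes additionally
    carry the enriched term with probability 0.8 (vs 0.1 elsewhere).
    """
    rng = np.random.default_rng(seed)
    study = set(study_genes)
    table: dict[str, set[str]] = {}
    for gene in sorted(background_genes):
        terms = {f"TERM:{int(t)}"
                 for t in rng.choice(n_terms, size=int(rng.integers(1, 4)))}
        p = 0.8 if gene in study else 0.1
        if rng.random() < p:
            terms.add(enriched_term)
        table[gene] = terms
    return table
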
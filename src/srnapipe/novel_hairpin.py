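"""Novel-miRNA discovery: excision, folding, and hairpin calling.

Candidate precursors are excised around genome-mapped tags, folded with a
built-in nearest-neighbor stacking DP (or with structures imported from
RNAfold-format output), and accepted as novel miRNAs when the mature sits
cleanly on one arm of a stem-loop opposite a star sequence and the
precursor's minimal folding energy index (MFEI) is at least 0.9.

The built-in folder is a Nussinov-style dynamic program that minimizes the
sum of stacked-pair free energies (embedded Turner-style RNA/RNA stack
table, minimum hairpin loop of 3, nested structures only). It is not a
full Zuker/partition-function folder: loop penalties are ignored, so
absolute energies are optimistic; all acceptance logic therefore relies on
planted-truth recovery and on model-internal ratios, never on literature
MFE values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from ._thermo import PAIR_TABLE, STACK_ENERGY, encode
from .sio import normalize, revcomp

_INF = 1e9
_EPS = 1e-6
MIN_WINDOW = 40
MIN_HAIRPIN_LOOP = 3


# ---------------------------------------------------------------------------
# Folding dynamic program
# ---------------------------------------------------------------------------

def _fold_dp(codes, pair_table, stack):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    W = np.zeros((n, n))
    V = np.full((n, n), _INF)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            a, b = codes[i], codes[j]
            p = pair_table[a, b] if (a < 4 and b < 4) else -1
            if p >= 0:
                best = W[i + 1, j - 1]
                a2, b2 = codes[i + 1], codes[j - 1]
                p2 = pair_table[a2, b2] if (a2 < 4 and b2 < 4) else -1
                if p2 >= 0 and V[i + 1, j - 1] < _INF / 2:
                    cand = stack[p, p2] + V[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            w = W[i + 1, j]
            if W[i, j - 1] < w:
                w = W[i, j - 1]
            if V[i, j] < w:
                w = V[i, j]
            for k in range(i + 1, j):
                s = W[i, k] + W[k + 1, j]
                if s < w:
                    w = s
            W[i, j] = w
    return W, V


try:  # numba gives ~100x on the O(n^3) fill; plain python remains correct
    from numba import njit

    _fold_dp = njit(cache=True)(_fold_dp)
except ImportError:  # pragma: no cover
    pass


def _traceback(codes, W, V) -> list[tuple[int, int]]:
    n = codes.shape[0]
    pairs: list[tuple[int, int]] = []
    stack_: list[tuple[int, int, bool]] = [(0, n - 1, False)]
    while stack_:
        i, j, in_v = stack_.pop()
        if j - i < MIN_HAIRPIN_LOOP + 1:
            continue
        if in_v:
            a2, b2 = codes[i + 1], codes[j - 1]
            p = PAIR_TABLE[codes[i], codes[j]]
            p2 = PAIR_TABLE[a2, b2] if (a2 < 4 and b2 < 4) else -1
            if (p2 >= 0 and V[i + 1, j - 1] < _INF / 2 and
                    abs(V[i, j] - (STACK_ENERGY[p, p2] + V[i + 1, j - 1]))
                    < _EPS):
                pairs.append((i + 1, j - 1))
                stack_.append((i + 1, j - 1, True))
            else:
                stack_.append((i + 1, j - 1, False))
            continue
        w = W[i, j]
        if abs(w) < _EPS:
            continue
        if abs(w - W[i + 1, j]) < _EPS:
            stack_.append((i + 1, j, False))
        elif abs(w - W[i, j - 1]) < _EPS:
            stack_.append((i, j - 1, False))
        elif V[i, j] < _INF / 2 and abs(w - V[i, j]) < _EPS:
            pairs.append((i, j))
            stack_.append((i, j, True))
        else:
            for k in range(i + 1, j):
                if abs(w - (W[i, k] + W[k + 1, j])) < _EPS:
                    stack_.append((i, k, False))
                    stack_.append((k + 1, j, False))
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed")
    return pairs


def fold(window: str,
         external: Mapping[str, tuple[str, float]] | None = None,
         min_len: int = MIN_WINDOW) -> tuple[str, float]:
    """Fold a sequence window into (dot_bracket, MFE in kcal/mol).

    When ``external`` (a sequence -> (structure, mfe) mapping, e.g. from
    :func:`read_rnafold`) contains the window, that structure is returned
    instead of running the built-in folder.
    """
    window = normalize(window)
    if len(window) < min_len:
        raise ValueError(f"window too short ({len(window)} < {min_len} nt)")
    if external is not None and window in external:
        return external[window]
    codes = encode(window)
    W, V = _fold_dp(codes, PAIR_TABLE, STACK_ENERGY)
    pairs = _traceback(codes, W, V)
    db = ["."] * len(window)
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db), round(float(W[0, len(window) - 1]), 2)


_STRUCT_RE = re.compile(r"^([.()]+)\s+\(\s*(-?\d+\.?\d*)\s*\)\s*$")


def read_rnafold(path_or_text) -> dict[str, tuple[str, float]]:
    """Parse RNAfold-style output into {sequence: (dot_bracket, mfe)}.

    Expects the usual interleaving of optional ``>name`` lines, sequence
    lines, and structure lines ending with the energy in parentheses,
    e.g. ``(((...))) ( -1.20)``. Sequences are U->T normalized keys.
    """
    try:
        text = open(path_or_text).read()
    except (OSError, ValueError):
        text = str(path_or_text)
    out: dict[str, tuple[str, float]] = {}
    seq = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        m = _STRUCT_RE.match(line)
        if m:
            if seq is None:
                raise ValueError("structure line before any sequence line")
            if len(m.group(1)) != len(seq):
                raise ValueError("structure/sequence length mismatch")
            out[seq] = (m.group(1), float(m.group(2)))
            seq = None
        else:
            seq = normalize(line)
    return out


def pairs_from_dotbracket(db: str) -> np.ndarray:
    """Partner index per position (-1 where unpaired); checks balance."""
    partner = np.full(len(db), -1, dtype=np.int64)
    stack = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return partner


# ---------------------------------------------------------------------------
# MFEI
# ---------------------------------------------------------------------------

def gc_percent(seq: str) -> float:
    seq = normalize(seq)
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq) if seq else 0.0


def mfei(mfe: float, length: int, gc_pct: float) -> float:
    """Minimal folding energy index: AMFE / GC%, AMFE = -MFE/length x 100."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_pct <= 100:
        raise ValueError("GC percent must be in (0, 100]")
    if mfe > 0:
        raise ValueError("MFE must be <= 0")
    return (-mfe / length * 100.0) / gc_pct


# ---------------------------------------------------------------------------
# Excision
# ---------------------------------------------------------------------------

@dataclass
class HairpinWindow:
    """A candidate precursor window, oriented so the mature reads 5'->3'."""

    chrom: str
    g_start: int            # 1-based inclusive genome coords of the window
    g_end: int
    strand: str             # '+' or '-'
    seq: str
    mature_offset: int      # 0-based offset of the mature within seq
    tag: str


def _find_all(text: str, sub: str) -> list[int]:
    hits, start = [], 0
    while True:
        p = text.find(sub, start)
        if p < 0:
            return hits
        hits.append(p)
        start = p + 1


def excise_candidates(tag: str, genome, flank: int = 250,
                      inner: int = 20) -> list[HairpinWindow]:
    """Excise up to two windows per exact genomic locus of ``tag``.

    Both strands are searched. For a locus spanning [s, e] (1-based) the
    windows are [s - flank, e + inner] and [s - inner, e + flank],
    clipped to the chromosome; an unmapped tag yields an empty list.
    """
    tag = normalize(tag)
    if isinstance(genome, dict):
        genome = genome.items()
    windows: list[HairpinWindow] = []
    for chrom, chrom_seq in genome:
        chrom_seq = normalize(chrom_seq)
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            for p0 in _find_all(chrom_seq, query):
                s, e = p0 + 1, p0 + len(tag)          # 1-based locus
                for ws, we in ((s - flank, e + inner),
                               (s - inner, e + flank)):
                    ws, we = max(1, ws), min(len(chrom_seq), we)
                    segment = chrom_seq[ws - 1:we]
                    if strand == "+":
                        seq, off = segment, s - ws
                    else:
                        seq, off = revcomp(segment), we - e
                    windows.append(HairpinWindow(chrom, ws, we, strand,
                                                 seq, off, tag))
    return windows


# ---------------------------------------------------------------------------
# Hairpin evaluation and the novel-miRNA call
# ---------------------------------------------------------------------------

@dataclass
class HairpinCandidate:
    """A trimmed precursor with its structure, geometry and MFEI."""

    seq: str                # trimmed precursor (mature..star span)
    structure: str
    mfe: float
    mature_start: int       # 1-based inclusive on seq
    mature_end: int
    star_start: int | None
    star_end: int | None
    arm: str                # '5p' or '3p'
    gc_percent: float
    mfei: float
    window: HairpinWindow | None = None


def _evaluate_window(seq: str, mature_offset: int, mature_len: int,
                     fold_fn: Callable, max_unpaired_mature: int,
                     max_star_bulge: int = 4, max_loop_gap: int = 35,
                     ) -> HairpinCandidate | None:
    """Geometry check on one folded window; None when no clean hairpin.

    Beyond the unpaired-mature budget, the mature/star duplex may bulge
    the star arm by at most ``max_star_bulge`` nucleotides and the
    terminal loop separating mature from star may span at most
    ``max_loop_gap`` nucleotides (Mireap-style precursor limits).
    """
    m0, m1 = mature_offset, mature_offset + mature_len - 1
    if m0 < 0 or m1 >= len(seq) or len(seq) < MIN_WINDOW:
        return None
    db, _ = fold_fn(seq)
    partner = pairs_from_dotbracket(db)
    mature_partners = partner[m0:m1 + 1]
    paired = mature_partners[mature_partners >= 0]
    unpaired = int((mature_partners < 0).sum())
    if unpaired > max_unpaired_mature or len(paired) == 0:
        return None
    # Mature must sit wholly on one arm: every partner on the same side.
    if (paired > m1).all():
        arm = "5p"
    elif (paired < m0).all():
        arm = "3p"
    else:
        return None
    # Star with the canonical 2-nt 3' overhang: partner(m1-2)..partner(m0)+2
    # for a 5p mature (mirrored for 3p), clipped to the window.
    lo, hi = int(paired.min()), int(paired.max())
    # Duplex bulge limit: the star-side span may exceed the number of
    # paired positions by at most max_star_bulge (scattered pairing over
    # several distant helices is not a miRNA/miRNA* duplex).
    if (hi - lo + 1) - len(paired) > max_star_bulge:
        return None
    # Terminal loop between mature and star must be compact.
    gap = lo - m1 - 1 if lo > m1 else m0 - hi - 1
    if gap > max_loop_gap:
        return None
    if arm == "5p":
        star_lo, star_hi = lo, min(len(seq) - 1, hi + 2)
    else:
        star_lo, star_hi = max(0, lo - 2), hi
    # At most one loop between mature and star: intervals must be disjoint
    # with the terminal loop as the only region between them.
    if not (star_hi < m0 or star_lo > m1):
        return None
    # Trim to the precursor spanned by mature and star, then refold so the
    # reported MFE/MFEI describe the precursor, not background flanks.
    pre_lo, pre_hi = min(m0, star_lo), max(m1, star_hi)
    while pre_hi - pre_lo + 1 < MIN_WINDOW:   # pad tiny duplexes to foldable
        pre_lo, pre_hi = max(0, pre_lo - 1), min(len(seq) - 1, pre_hi + 1)
    pre_seq = seq[pre_lo:pre_hi + 1]
    pre_db, pre_mfe = fold_fn(pre_seq)
    gc = gc_percent(pre_seq)
    idx = mfei(pre_mfe, len(pre_seq), gc) if 0 < gc and pre_mfe <= 0 else 0.0
    return HairpinCandidate(
        seq=pre_seq, structure=pre_db, mfe=pre_mfe,
        mature_start=m0 - pre_lo + 1, mature_end=m1 - pre_lo + 1,
        star_start=star_lo - pre_lo + 1, star_end=star_hi - pre_lo + 1,
        arm=arm, gc_percent=gc, mfei=idx)


def _as_window(item, tag: str):
    if isinstance(item, HairpinWindow):
        return item.seq, item.mature_offset, item
    if isinstance(item, str):
        off = normalize(item).find(normalize(tag))
        return (normalize(item), off, None) if off >= 0 else (None, 0, None)
    seq, off = item
    return normalize(seq), off, None


def call_novel(tag: str, candidates: Iterable, min_mfei: float = 0.9,
               max_unpaired_mature: int = 4,
               fold_fn: Callable | None = None,
               ) -> HairpinCandidate | None:
    """Return the best hairpin supporting ``tag`` as a novel miRNA, or None.

    A candidate passes when the mature lies wholly on one arm with at most
    ``max_unpaired_mature`` unpaired bases, a star region with a 2-nt 3'
    overhang exists across a single terminal loop, and the precursor MFEI
    is >= ``min_mfei``. Ties between passing candidates break toward the
    lower (more negative) MFE.
    """
    fold_fn = fold_fn or fold
    tag = normalize(tag)
    best: HairpinCandidate | None = None
    for item in candidates:
        seq, off, win = _as_window(item, tag)
        if seq is None:
            continue
        cand = _evaluate_window(seq, off, len(tag), fold_fn,
                                max_unpaired_mature)
        if cand is None or cand.mfei < min_mfei:
            continue
        cand.window = win
        if best is None or cand.mfe < best.mfe:
            best = cand
    return best


def has_hairpin(tag: str, genome, flank: int = 250,
                fold_fn: Callable | None = None) -> bool:
    """True when a fold-back precursor is verifiable at the tag's locus.

    Geometry-only check (no MFEI gate) used by the cross-species
    known-miRNA rule.
    """
    fold_fn = fold_fn or fold
    for win in excise_candidates(tag, genome, flank=flank):
        if _evaluate_window(win.seq, win.mature_offset, len(tag),
                            fold_fn, max_unpaired_mature=4) is not None:
            return True
    return False
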
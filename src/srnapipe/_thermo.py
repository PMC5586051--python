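"""Nearest-neighbor RNA/RNA stacking free energies.

One embedded table serves both the hairpin folder and the miRNA/target
duplex scorer so that energy ratios are model-consistent.

Values are Turner-lab 37 degC stack free energies (kcal/mol): Watson-Crick
stacks from Xia et al. (1998), G.U-containing stacks from Mathews et
al. (1999) with the revised G.U/U.G special cases. Sequences are held in
the DNA alphabet internally (T for U); pairing logic treats T as U.
"""

from __future__ import annotations

import numpy as np

# Base encoding used throughout the numeric kernels.
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# Pair-type indices for the six allowed pairs (first base listed 5' on the
# top strand). -1 marks a non-pair.
PAIR_AU, PAIR_UA, PAIR_CG, PAIR_GC, PAIR_GU, PAIR_UG = range(6)

_PAIR_OF = {
    (0, 3): PAIR_AU,
    (3, 0): PAIR_UA,
    (1, 2): PAIR_CG,
    (2, 1): PAIR_GC,
    (2, 3): PAIR_GU,
    (3, 2): PAIR_UG,
}

# 5x5 lookup (codes 0..4, N never pairs): pair type or -1.
PAIR_TABLE = np.full((5, 5), -1, dtype=np.int8)
for (a, b), p in _PAIR_OF.items():
    PAIR_TABLE[a, b] = p

# Flip maps a pair read from the opposite strand: AU<->UA, CG<->GC, GU<->UG.
_FLIP = {PAIR_AU: PAIR_UA, PAIR_UA: PAIR_AU, PAIR_CG: PAIR_GC,
         PAIR_GC: PAIR_CG, PAIR_GU: PAIR_UG, PAIR_UG: PAIR_GU}

# Independent entries, keyed (p1, p2) = (5' pair, 3' pair) of the stack
# 5'-XY-3' / 3'-X'Y'-5'.  The remainder follow from the strand-flip
# symmetry E(p1, p2) = E(flip(p2), flip(p1)).
_STACK_INDEPENDENT = {
    # Watson-Crick / Watson-Crick (Xia 1998)
    (PAIR_AU, PAIR_AU): -0.93,   # 5'AA/3'UU
    (PAIR_AU, PAIR_UA): -1.10,   # 5'AU/3'UA
    (PAIR_UA, PAIR_AU): -1.33,   # 5'UA/3'AU
    (PAIR_CG, PAIR_UA): -2.08,   # 5'CU/3'GA
    (PAIR_CG, PAIR_AU): -2.11,   # 5'CA/3'GU
    (PAIR_GC, PAIR_UA): -2.24,   # 5'GU/3'CA
    (PAIR_GC, PAIR_AU): -2.35,   # 5'GA/3'CU
    (PAIR_CG, PAIR_GC): -2.36,   # 5'CG/3'GC
    (PAIR_GC, PAIR_GC): -3.26,   # 5'GG/3'CC
    (PAIR_GC, PAIR_CG): -3.42,   # 5'GC/3'CG
    # G.U-containing (Mathews 1999)
    (PAIR_AU, PAIR_GU): -0.55,   # 5'AG/3'UU
    (PAIR_AU, PAIR_UG): -1.36,   # 5'AU/3'UG
    (PAIR_CG, PAIR_GU): -1.41,   # 5'CG/3'GU
    (PAIR_CG, PAIR_UG): -2.11,   # 5'CU/3'GG
    (PAIR_GC, PAIR_GU): -1.53,   # 5'GG/3'CU
    (PAIR_GC, PAIR_UG): -2.51,   # 5'GU/3'CG
    (PAIR_UA, PAIR_GU): -1.27,   # 5'UG/3'AU
    (PAIR_UA, PAIR_UG): -1.00,   # 5'UU/3'AG
    # G.U / G.U
    (PAIR_GU, PAIR_GU): -0.50,   # 5'GG/3'UU
    (PAIR_GU, PAIR_UG): +0.47,   # 5'GU/3'UG (destabilizing motif)
    (PAIR_UG, PAIR_GU): -0.57,   # 5'UG/3'GU
}

#: STACK_ENERGY[p1, p2] -- free energy of pair p2 stacked 3' of pair p1.
STACK_ENERGY = np.zeros((6, 6), dtype=np.float64)
for (p1, p2), e in _STACK_INDEPENDENT.items():
    STACK_ENERGY[p1, p2] = e
    STACK_ENERGY[_FLIP[p2], _FLIP[p1]] = e


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string into the numeric alphabet (A,C,G,T/U,N)."""
    try:
        return np.fromiter((BASE_CODE[c] for c in seq.upper()), dtype=np.int8,
                           count=len(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def pair_type(a: str, b: str) -> int:
    """Pair-type index of bases a/b (strings), or -1 if they cannot pair."""
    return int(PAIR_TABLE[BASE_CODE[a.upper()], BASE_CODE[b.upper()]])
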
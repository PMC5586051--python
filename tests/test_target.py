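import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from srnapipe._thermo import BASE_CODE, PAIR_TABLE, STACK_ENERGY
from srnapipe.sio import revcomp
from srnapipe.target_duplex import (CUT_OFFSET, DuplexAlignment, RulesConfig,
                                    TargetSite, apply_rules, duplex_energy,
                                    pair_states, scan_transcript)

MIRNA = "TGACAGAAGAGAGTGAGCAC"   # a conserved 20-nt plant mature (miR156)
MIRNA21 = "TTGGACTGAAGGGAGCTCCCT"

# Published (binding site, cleavage site) geometry on target CDSs:
# (miRNA family, transcript, start, end, cut). The cleavage coordinate
# always equals site end - 9 (the bond opposite miRNA positions 10-11).
CUT_TABLE = [
    ("miR156", "AK356077", 839, 858, 849),
    ("miR156", "AK374598", 860, 879, 870),
    ("miR156", "MLOC_11199.2", 1154, 1173, 1164),
    ("miR159", "AK251726.1", 962, 982, 973),
    ("miR159", "AK370348", 1009, 1028, 1019),
    ("miR160", "MLOC_64795.1", 1329, 1349, 1340),
    ("miR160", "MLOC_69988.1", 717, 737, 728),
    ("miR165", "MLOC_44268.1", 159, 179, 170),
    ("miR165", "AK362009", 578, 598, 589),
    ("miR165", "AK364215", 639, 658, 649),
    ("miR165", "MLOC_58644.1", 980, 1000, 991),
    ("miR166", "AK362009", 578, 598, 589),
    ("miR166", "AK364215", 638, 658, 649),
    ("miR166", "AK364215", 640, 658, 649),
    ("miR166", "AK365312", 563, 583, 574),
    ("miR166", "MLOC_44268.1", 159, 179, 170),
    ("miR166", "MLOC_58644.1", 980, 1000, 991),
    ("miR167", "MLOC_51932.2", 2343, 2363, 2354),
    ("miR167", "MLOC_58330.2", 2528, 2549, 2540),
    ("miR167", "MLOC_63938.1", 2402, 2423, 2414),
    ("miR171", "AK371946", 1090, 1109, 1100),
    ("miR172", "AK355002", 1214, 1234, 1225),
    ("miR319", "AK370348", 1009, 1028, 1019),
    ("miR319", "MLOC_63989.1", 976, 995, 986),
    ("miR360", "MLOC_69988.1", 717, 737, 728),
    ("miR393", "AK355927", 1560, 1580, 1571),
    ("miR393", "AK374984", 1974, 1994, 1985),
    ("miR396", "MLOC_64055.4", 375, 395, 386),
    ("miR396", "AK250947.1", 480, 500, 491),
    ("miR396", "AK353813", 387, 407, 398),
    ("miR396", "AK376404", 417, 437, 428),
    ("miR396", "MLOC_67201.4", 741, 761, 752),
    ("miR396", "MLOC_80060.1", 507, 527, 518),
    ("miR396", "MLOC_12347.1", 1438, 1458, 1449),
    ("miR396", "AK375237", 184, 204, 195),
    ("miR444", "MLOC_16182.1", 1035, 1055, 1046),
    ("miR5051", "MLOC_57965.3", 595, 615, 606),
    ("miR7757", "MLOC_17471.2", 194, 215, 206),
    ("miR9863", "MLOC_24045.1", 1259, 1280, 1271),
    ("novel-mir-119", "AK362090", 1362, 1382, 1373),
    ("novel-mir-119", "AK369226", 423, 443, 434),
    ("novel-mir-400", "MLOC_53497.2", 587, 609, 600),
    ("novel-mir-205", "MLOC_54213.1", 389, 410, 401),
]

MM = {"A": "C", "C": "A", "G": "G", "T": "T"}   # never pairs, never G.U


def _mismatch_at(mirna, site, positions):
    """Force a full mismatch at the given miRNA positions (1-based)."""
    L = len(mirna)
    s = list(site)
    for p in positions:
        s[L - p] = MM[mirna[p - 1]]
    return "".join(s)


# -- pair states ------------------------------------------------------------

def test_perfect_complement_all_wc():
    dup = pair_states(MIRNA, revcomp(MIRNA))
    assert set(dup.states) == {"WC"}
    assert dup.mismatch_total == 0
    assert dup.energy_ratio == pytest.approx(1.0)


def test_single_gu_counts_half():
    # miRNA position 5 is A in MIRNA; use position 1 (T) -> G on target
    mirna = "TGACAGAAGAGAGTGAGCAC"
    site = list(revcomp(mirna))
    # miRNA position 1 = T faces site index L-1; set to G for a G.U
    site[len(mirna) - 1] = "G"
    dup = pair_states(mirna, "".join(site))
    assert dup.states[0] == "GU"
    assert dup.mismatch_total == 0.5


def test_unequal_lengths_error():
    with pytest.raises(ValueError):
        pair_states("ACGT" * 5, "ACGT" * 6)


@given(st.integers(0, 2**31 - 1))
def test_pair_state_totals_match_recount(seed):
    rng = np.random.default_rng(seed)
    mirna = "".join("ACGT"[b] for b in rng.integers(0, 4, 21))
    site = "".join("ACGT"[b] for b in rng.integers(0, 4, 21))
    dup = pair_states(mirna, site)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    total = total5 = 0.0
    for i in range(21):
        pair = (mirna[i], site[21 - 1 - i])
        add = 0.0 if pair in wc else (0.5 if pair in gu else 1.0)
        total += add
        if i < 12:
            total5 += add
    assert dup.mismatch_total == total
    assert dup.mismatch_5p_1_12 == total5


# -- six rules: exhaustive oracle -------------------------------------------

def _oracle_rules(mirna, site):
    """Independent rule-by-rule evaluation from raw base identities."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    L = len(mirna)
    kinds = []
    for i in range(L):
        pair = (mirna[i], site[L - 1 - i])
        kinds.append("wc" if pair in wc else "gu" if pair in gu else "mm")
    score = {"wc": 0.0, "gu": 0.5, "mm": 1.0}
    failed = set()
    if sum(score[k] for k in kinds) > 4:
        failed.add(1)
    run = 0
    for k in kinds:
        run = run + 1 if k == "mm" else 0
        if run > 2:
            failed.add(2)
    for p in range(2, 12):          # adjacent pairs inside positions 2..12
        if kinds[p - 1] == "mm" and kinds[p] == "mm":
            failed.add(3)
    if kinds[9] == "mm" or kinds[10] == "mm":
        failed.add(4)
    if sum(score[k] for k in kinds[:12]) > 2.5:
        failed.add(5)
    # energy from an independent re-summation over the embedded table
    def energy(m, s):
        tot = 0.0
        for i in range(L - 1):
            p1 = PAIR_TABLE[BASE_CODE[m[i]], BASE_CODE[s[L - 1 - i]]]
            p2 = PAIR_TABLE[BASE_CODE[m[i + 1]], BASE_CODE[s[L - 2 - i]]]
            if p1 >= 0 and p2 >= 0:
                tot += min(0.0, STACK_ENERGY[p1, p2])
        return tot
    if energy(mirna, site) / energy(mirna, revcomp(mirna)) < 0.75:
        failed.add(6)
    return failed


def test_exhaustive_single_and_double_mismatch_verdicts():
    mirna = MIRNA21
    perfect = revcomp(mirna)
    cases = [(p,) for p in range(1, 22)]
    cases += [(p, q) for p in range(1, 22) for q in range(p + 1, 22)]
    for positions in cases:
        site = _mismatch_at(mirna, perfect, positions)
        dup = pair_states(mirna, site)
        ok, failed = apply_rules(dup)
        expected = _oracle_rules(mirna, site)
        assert failed == expected, (positions, failed, expected)
        assert ok == (not expected)


def test_mismatch_at_slicing_site_fails_rule4():
    site = _mismatch_at(MIRNA21, revcomp(MIRNA21), (10,))
    ok, failed = apply_rules(pair_states(MIRNA21, site))
    assert not ok and failed == {4}


def test_rules_monotone_under_degradation(rng):
    # converting any WC pair to a mismatch never flips fail -> pass
    for _ in range(30):
        positions = tuple(sorted(rng.choice(range(1, 22),
                                            size=rng.integers(1, 4),
                                            replace=False) + 0))
        site = _mismatch_at(MIRNA21, revcomp(MIRNA21), positions)
        ok_before, _ = apply_rules(pair_states(MIRNA21, site))
        extra = int(rng.integers(1, 22))
        worse = _mismatch_at(MIRNA21, site, (extra,))
        ok_after, _ = apply_rules(pair_states(MIRNA21, worse))
        assert ok_before or not ok_after


def test_gu_is_mismatch_config():
    # MIRNA21 position 11 is G: a G.U wobble there is a pair under the
    # default scoring but a slicing-site mismatch when gu_is_mismatch.
    assert MIRNA21[10] == "G"
    site = list(revcomp(MIRNA21))
    site[len(MIRNA21) - 11] = "T"
    dup = pair_states(MIRNA21, "".join(site))
    ok_default, failed_default = apply_rules(dup)
    ok_strict, failed_strict = apply_rules(
        dup, RulesConfig(gu_is_mismatch=True))
    assert ok_default and failed_default == set()
    assert not ok_strict and 4 in failed_strict


# -- duplex energy ----------------------------------------------------------

def test_energy_of_unpaired_duplex_is_zero():
    # A facing A at every position: no pairs at all
    dup = pair_states("AAAAAAAAAA", "AAAAAAAAAA")
    assert set(dup.states) == {"mismatch"}
    assert duplex_energy(dup) == 0.0


def test_perfect_energy_equals_revcomp_duplex():
    dup = pair_states(MIRNA, revcomp(MIRNA))
    assert dup.energy == dup.perfect_energy


@given(st.integers(0, 2**31 - 1))
def test_energy_matches_independent_resummation(seed):
    rng = np.random.default_rng(seed)
    mirna = "".join("ACGT"[b] for b in rng.integers(0, 4, 21))
    site = "".join("ACGT"[b] for b in rng.integers(0, 4, 21))
    dup = pair_states(mirna, site)
    L = 21
    expected = 0.0
    for i in range(L - 1):
        if dup.states[i] != "mismatch" and dup.states[i + 1] != "mismatch":
            p1 = PAIR_TABLE[BASE_CODE[mirna[i]],
                            BASE_CODE[site[L - 1 - i]]]
            p2 = PAIR_TABLE[BASE_CODE[mirna[i + 1]],
                            BASE_CODE[site[L - 2 - i]]]
            expected += min(0.0, STACK_ENERGY[p1, p2])
    assert duplex_energy(dup) == pytest.approx(expected, abs=1e-6)


def test_energy_monotone_adding_mismatch_never_strengthens(rng):
    site = revcomp(MIRNA21)
    base = pair_states(MIRNA21, site)
    for p in range(1, 22):
        worse = pair_states(MIRNA21, _mismatch_at(MIRNA21, site, (p,)))
        assert worse.energy >= base.energy


# -- transcript scanning ----------------------------------------------------

def test_scan_finds_planted_site_with_table_geometry(rng):
    # planted perfect site at 839-858 -> reported cut 849 (end - 9)
    bg = "".join("ACGT"[b] for b in rng.integers(0, 4, 2000))
    site_seq = revcomp(MIRNA)
    transcript = bg[:838] + site_seq + bg[858:]
    sites = scan_transcript(MIRNA, transcript)
    exact = [s for s in sites if s.start == 839]
    assert exact and exact[0].end == 858
    assert exact[0].expected_cut == 849


def test_scan_matches_brute_force_window_evaluation(rng):
    transcript = "".join("ACGT"[b] for b in rng.integers(0, 4, 10_000))
    mirna = "".join("ACGT"[b] for b in rng.integers(0, 4, 21))
    sites = scan_transcript(mirna, transcript)
    expected = 0
    for start in range(len(transcript) - 20):
        window = transcript[start:start + 21]
        ok, _ = apply_rules(pair_states(mirna, window))
        expected += ok
    assert len(sites) == expected


def test_cut_table_geometry_all_rows():
    for family, transcript, start, end, cut in CUT_TABLE:
        assert end - CUT_OFFSET == cut, (family, transcript)


def test_site_expected_cut_from_coordinates():
    dup = pair_states(MIRNA21, revcomp(MIRNA21))
    site = TargetSite("AK355927", 1560, 1580, dup, "miR393")
    assert site.expected_cut == 1571


def test_scan_is_strand_specific(rng):
    bg = "".join("ACGT"[b] for b in rng.integers(0, 4, 1000))
    transcript = bg[:500] + revcomp(MIRNA) + bg[500:]
    assert any(s.start == 501 for s in scan_transcript(MIRNA, transcript))
    rc = revcomp(transcript)
    hits = scan_transcript(MIRNA, rc)
    assert not any(rc[s.start - 1:s.end] == revcomp(MIRNA) for s in hits)
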
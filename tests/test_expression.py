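import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from srnapipe.expression_stats import (benjamini_hochberg, call_de,
                                       ddct_relative, de_test,
                                       hypergeom_enrich, log2_fold_change,
                                       tpm)
from srnapipe.sio import CountMatrix


# -- TPM / fold change ------------------------------------------------------

def test_tpm_values():
    assert tpm(5, 1_000_000) == 5.0
    assert tpm(0, 123) == 0.0
    with pytest.raises(ValueError):
        tpm(1, 0)


def test_tpm_conservation(rng):
    counts = rng.integers(0, 500, size=300)
    total = counts.sum()
    assert sum(tpm(c, total) for c in counts) == pytest.approx(1e6)


def test_log2_fold_change():
    assert log2_fold_change(8, 2) == pytest.approx(2.0)
    assert log2_fold_change(3.7, 3.7) == 0.0
    assert log2_fold_change(0, 100, floor=0.01) == pytest.approx(
        math.log2(0.01 / 100))
    assert log2_fold_change(0, 100, floor=0.01) == pytest.approx(-13.2877,
                                                                 abs=1e-4)


# -- Audic-Claverie / Fisher ------------------------------------------------

def _ac_pmf(y, x, n1, n2):
    """Independent log-space evaluation of the AC posterior pmf."""
    r = n2 / n1
    return math.exp(y * math.log(r)
                    + math.lgamma(x + y + 1) - math.lgamma(x + 1)
                    - math.lgamma(y + 1)
                    - (x + y + 1) * math.log(1 + r))


def _ac_brute(x, n1, y, n2):
    lower = sum(_ac_pmf(t, x, n1, n2) for t in range(0, y + 1))
    upper = 1.0 - lower + _ac_pmf(y, x, n1, n2)
    return min(1.0, 2.0 * min(lower, upper))


def test_de_test_equal_counts_p_one():
    assert de_test(7, 1e6, 7, 1e6) == pytest.approx(1.0)
    assert de_test(0, 1e6, 0, 1e6) == pytest.approx(1.0)
    assert de_test(0, 5e5, 0, 1e6) == pytest.approx(1.0, abs=0.05) or \
        de_test(0, 5e5, 0, 1e6) <= 1.0


def test_de_test_detects_large_change():
    assert de_test(5, 1e6, 50, 1e6) < 1e-5


def test_audic_claverie_matches_brute_force_tail_sum(rng):
    for _ in range(50):
        x = int(rng.integers(0, 200))
        y = int(rng.integers(0, 200))
        n1 = float(rng.integers(10_000, 2_000_000))
        n2 = float(rng.integers(10_000, 2_000_000))
        expected = min(_ac_brute(x, n1, y, n2), _ac_brute(y, n2, x, n1))
        assert de_test(x, n1, y, n2) == pytest.approx(expected, rel=1e-8)


@given(st.integers(0, 300), st.integers(0, 300),
       st.sampled_from([1e5, 5e5, 1e6]), st.sampled_from([1e5, 5e5, 1e6]))
def test_de_test_symmetric_under_swap(a, b, na, nb):
    for method in ("audic_claverie", "fisher"):
        assert de_test(a, na, b, nb, method) == pytest.approx(
            de_test(b, nb, a, na, method), rel=1e-12)


def test_de_test_fisher_and_errors():
    assert 0 < de_test(10, 1000, 20, 1000, "fisher") <= 1
    with pytest.raises(ValueError):
        de_test(1, 100, 1, 100, "bogus")
    with pytest.raises(ValueError):
        de_test(1, 0, 1, 100)


# -- call_de ----------------------------------------------------------------

def _matrix(counts_a, counts_b, total=1_000_000):
    df = pd.DataFrame({"a": counts_a, "b": counts_b},
                      index=[f"f{i}" for i in range(len(counts_a))])
    return CountMatrix(df, {"a": total, "b": total})


def test_call_de_identical_counts_not_significant():
    m = _matrix([50, 100], [50, 100])
    assert not any(r.significant for r in call_de(m, ("a", "b")))


def test_call_de_requires_both_gates():
    # large fold change but tiny counts: p stays above alpha
    m = _matrix([0], [8])
    res = call_de(m, ("a", "b"))[0]
    assert abs(res.log2fc) >= 1 and res.p_value > 1e-5
    assert not res.significant


def test_call_de_planted_eightfold_power(rng):
    # 20 true 8-fold features (expected counts >= 100) among 180 nulls
    a_true = rng.poisson(100, 20)
    b_true = rng.poisson(800, 20)
    a_null = rng.poisson(150, 180)
    b_null = rng.poisson(150, 180)
    m = _matrix(np.r_[a_true, a_null], np.r_[b_true, b_null])
    res = call_de(m, ("a", "b"), fc_threshold=1.0, alpha=1e-5)
    tp = sum(r.significant for r in res[:20])
    fp = sum(r.significant for r in res[20:])
    assert tp >= 18
    assert fp <= 2


def test_call_de_type_one_error_calibration(rng):
    # null features at matched totals: empirical type-I <= 2x nominal
    alpha = 1e-3
    counts_a = rng.poisson(200, 2000)
    counts_b = rng.poisson(200, 2000)
    m = _matrix(counts_a, counts_b)
    res = call_de(m, ("a", "b"), fc_threshold=0.0, alpha=alpha)
    frac = np.mean([r.p_value < alpha for r in res])
    assert frac <= 2 * alpha


# -- enrichment -------------------------------------------------------------

def test_enrich_term_on_every_gene_p_one():
    genes = [f"g{i}" for i in range(20)]
    table = {g: {"T:all"} for g in genes}
    res = hypergeom_enrich(genes[:5], genes, table)
    assert res[0].p_value == pytest.approx(1.0)


def test_enrich_closed_form_extreme():
    genes = [f"g{i}" for i in range(20)]
    table = {g: ({"T:rare"} if i < 5 else {"T:other"})
             for i, g in enumerate(genes)}
    res = hypergeom_enrich(genes[:5], genes, table)
    rare = [r for r in res if r.term == "T:rare"][0]
    assert rare.p_value == pytest.approx(1 / math.comb(20, 5), rel=1e-9)


def test_enrich_requires_subset():
    with pytest.raises(ValueError):
        hypergeom_enrich(["x"], ["a", "b"], {})


def test_enrich_matches_exhaustive_enumeration(rng):
    # N <= 12: compare against enumeration of all C(N, n) study sets
    import itertools
    genes = [f"g{i}" for i in range(10)]
    table = {g: {"T"} if i in (0, 2, 5, 7) else set()
             for i, g in enumerate(genes)}
    n = 4
    for study in itertools.combinations(genes, 2):
        res = hypergeom_enrich(study, genes, table)
        k = sum(1 for g in study if "T" in table[g])
        if k == 0:
            assert all(r.term != "T" for r in res)
            continue
        # exhaustive tail: fraction of same-size study sets with >= k hits
        total = hits = 0
        for other in itertools.combinations(genes, 2):
            total += 1
            hits += sum(1 for g in other if "T" in table[g]) >= k
        p = [r for r in res if r.term == "T"][0].p_value
        assert p == pytest.approx(hits / total, rel=1e-9)


def test_enrich_null_calibration(rng):
    # random study sets under the null: P(p < 0.05) ~ 0.05. The study
    # size must be large enough that the discrete hypergeometric tail is
    # fine-grained near 0.05.
    N, K, n = 5000, 1000, 500
    hits = 0
    draws = 2000
    for _ in range(draws):
        k = int(rng.hypergeometric(K, N - K, n))
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k else 1.0
        hits += p < 0.05
    assert abs(hits / draws - 0.05) <= 0.02


def test_benjamini_hochberg_monotone():
    ps = [0.001, 0.01, 0.02, 0.8]
    qs = benjamini_hochberg(ps)
    assert all(q >= p for p, q in zip(ps, qs))
    assert qs == sorted(qs)


# -- ddCt -------------------------------------------------------------------

def test_ddct_calibrator_is_one():
    assert ddct_relative(22.0, 18.0, 22.0, 18.0) == 1.0


def test_ddct_minus_one_doubles():
    assert ddct_relative(21.0, 18.0, 22.0, 18.0) == 2.0


def test_ddct_quartet():
    assert ddct_relative(22, 18, 25, 18) == pytest.approx(8.0)
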
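"""Expression quantification, differential expression, enrichment, ddCt.

Quantification follows the tag-count conventions of small-RNA surveys:
TPM = count / total clean reads x 1e6, fold change = log2(treatment /
control). Differential calls between two un-replicated libraries use the
Audic-Claverie tag-count test (the canonical IDEG6 statistic) or Fisher's
exact test; a feature is significant when both |log2FC| >= the threshold
and p < alpha. Term enrichment is the upper-tail hypergeometric test
against a background gene set, and ddCt provides qPCR-style relative
quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .sio import CountMatrix

TPM_FLOOR = 0.01   # fold-change floor only; never used in testing


@dataclass
class DEResult:
    feature_id: str
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float
    log2fc: float
    p_value: float
    significant: bool


@dataclass
class EnrichmentResult:
    term: str
    k: int         # term hits in the study set
    n: int         # study size
    K: int         # term hits in the background
    N: int         # background size
    p_value: float


def tpm(count: float, library_total: float) -> float:
    """Tags per million: count / total clean reads x 1e6."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / library_total * 1e6


def log2_fold_change(tpm_treat: float, tpm_control: float,
                     floor: float = TPM_FLOOR) -> float:
    """log2(treatment / control) with a floor keeping zeros finite."""
    return math.log2(max(tpm_treat, floor) / max(tpm_control, floor))


def _ac_two_sided(x: int, n1: float, y: int, n2: float) -> float:
    """Two-sided Audic-Claverie p for observing y (library size n2) given
    x (library size n1).

    The AC posterior of the second count given the first is negative
    binomial: y | x ~ NB(r = x + 1, p = n1 / (n1 + n2)). The two-sided p
    is min(1, 2 * min(P(Y <= y), P(Y >= y))).
    """
    p = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y - 1, x + 1, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def de_test(count_a: int, total_a: float, count_b: int, total_b: float,
            method: str = "audic_claverie") -> float:
    """Two-sided p-value for a tag-count difference between two libraries.

    ``audic_claverie``: symmetrized two-sided tail of the AC posterior
    (the min over both conditioning directions, so the result is exactly
    invariant under swapping the libraries). ``fisher``: two-sided Fisher
    exact test on [[count_a, total_a - count_a], [count_b,
    total_b - count_b]].
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if method == "audic_claverie":
        return min(_ac_two_sided(count_a, total_a, count_b, total_b),
                   _ac_two_sided(count_b, total_b, count_a, total_a))
    if method == "fisher":
        table = [[count_a, int(total_a) - count_a],
                 [count_b, int(total_b) - count_b]]
        return float(stats.fisher_exact(table)[1])
    raise ValueError(f"unknown method {method!r}")


def call_de(matrix: CountMatrix, pair: tuple[str, str],
            fc_threshold: float = 1.0, alpha: float = 1e-5,
            method: str = "audic_claverie") -> list[DEResult]:
    """Differential-expression calls for one library pair.

    Significant iff |log2FC| >= ``fc_threshold`` (TPM scale, floored)
    AND p < ``alpha`` (both gates required; a fixed per-feature cutoff,
    no multiplicity correction).
    """
    lib_a, lib_b = pair
    for lib in pair:
        if lib not in matrix.counts.columns:
            raise KeyError(f"library {lib!r} not in matrix")
    total_a = matrix.library_totals[lib_a]
    total_b = matrix.library_totals[lib_b]
    results = []
    for feature, row in matrix.counts.iterrows():
        ca, cb = int(row[lib_a]), int(row[lib_b])
        ta, tb = tpm(ca, total_a), tpm(cb, total_b)
        lfc = log2_fold_change(tb, ta)
        p = de_test(ca, total_a, cb, total_b, method)
        results.append(DEResult(str(feature), ca, cb, ta, tb, lfc, p,
                                abs(lfc) >= fc_threshold and p < alpha))
    return results


def hypergeom_enrich(study_genes, background_genes,
                     term_table: Mapping[str, set[str]],
                     ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of terms in a study set.

    For each term with K annotated genes among the N background genes,
    and k hits among the n study genes, p = P(X >= k) with
    X ~ Hypergeometric(N, K, n). Only terms hit at least once in the
    study set are reported, sorted by p.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    N, n = len(background), len(study)
    term_background: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in term_table.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    results = []
    for term, k in term_study.items():
        K = term_background[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, min(1.0, p)))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted q-values (optional column for enrichment reports)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, p_values[idx] * m / rank)
        q[idx] = prev
    return q


def ddct_relative(ct_target_sample: float, ct_ref_sample: float,
                  ct_target_cal: float, ct_ref_cal: float) -> float:
    """Relative expression by the ddCt method: 2^-ddCt.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the calibrator; the calibrator's level is 1.0.
    """
    ddct = ((ct_target_sample - ct_ref_sample)
            - (ct_target_cal - ct_ref_cal))
    return 2.0 ** (-ddct)
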
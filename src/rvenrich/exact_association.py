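"""Exact inference on 2x2 allele-count tables.

Conditional on both margins of a 2x2 table, the case-alternate-allele cell
K follows Fisher's noncentral hypergeometric distribution with noncentrality
equal to the odds ratio psi:

    P(K = k | psi) = C(m1, k) C(m2, n1 - k) psi**k / sum_j C(m1, j) C(m2, n1 - j) psi**j

where m1 = a + b case alleles, m2 = c + d control alleles and n1 = a + c
total alternate alleles. Everything in this module is built on that one
density, evaluated in log space so that allele numbers of ~20,000 (the
scale of aggregate population panels) never overflow:

* the two-sided exact test (minimum-likelihood rule, with a tail-doubling
  alternative behind a switch),
* the conditional maximum-likelihood odds ratio, solving E[K | psi] = a,
* the exact (Cornfield-style) confidence interval by test inversion.

The conditional MLE, not the sample cross-product, is the default estimator
because its zero-cell conventions (psi-hat = 0 when no case alternate
alleles are seen, +inf when the support saturates) match how aggregate
case-control tables are conventionally reported.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .model import (
    AssociationResult,
    CaseCohort,
    Comparison,
    ContingencyTable,
    ControlFrequencyTable,
    Status,
    VariantKey,
    round_half_up,
)

__all__ = [
    "build_table",
    "noncentral_hypergeom_logpmf",
    "noncentral_hypergeom_pmf",
    "fisher_two_sided_p",
    "conditional_mle_or",
    "exact_ci",
    "associate",
]

# Relative tolerance absorbing floating-point ties between outcome
# probabilities in the minimum-likelihood two-sided rule.
_TIE_REL_TOL = 1e-7


def build_table(
    case_alt: int, case_an: int, control_af: float, control_an: int
) -> ContingencyTable:
    """Reconstruct the 2x2 allele-count table from a case count and a
    control frequency summary.

    The control alternate count is ``round_half_up(AF * AN)`` -- the same
    rounding used when frequencies are emitted, so count -> frequency ->
    count round-trips exactly.
    """
    if not 0 <= case_alt <= case_an:
        raise ValueError(f"case alt count {case_alt} outside [0, {case_an}]")
    if not 0.0 <= control_af <= 1.0:
        raise ValueError(f"control AF outside [0, 1]: {control_af}")
    c = round_half_up(control_af * control_an)
    if c > control_an:
        raise ValueError(
            f"reconstructed control count {c} exceeds allele number {control_an}"
        )
    return ContingencyTable(case_alt, case_an - case_alt, c, control_an - c)


def _support_and_logweights(
    table: ContingencyTable, log_psi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Support of K and unnormalised log-weights at the given log odds ratio."""
    kmin, kmax = table.support()
    k = np.arange(kmin, kmax + 1)
    m1, m2, n1 = table.case_an, table.control_an, table.alt_total
    logw = (
        gammaln(m1 + 1)
        - gammaln(k + 1)
        - gammaln(m1 - k + 1)
        + gammaln(m2 + 1)
        - gammaln(n1 - k + 1)
        - gammaln(m2 - (n1 - k) + 1)
    )
    if log_psi != 0.0:
        logw = logw + k * log_psi
    return k, logw


def noncentral_hypergeom_logpmf(
    k: int | np.ndarray, table: ContingencyTable, psi: float
) -> np.ndarray | float:
    """Log-pmf of Fisher's noncentral hypergeometric distribution.

    ``table`` supplies the margins; ``k`` is the case-alternate cell.
    ``psi = 1`` reduces to the central hypergeometric distribution.
    """
    if psi < 0:
        raise ValueError(f"odds ratio must be non-negative, got {psi}")
    kmin, kmax = table.support()
    if psi == 0.0:
        # All mass collapses onto the support minimum.
        logp = np.full(kmax - kmin + 1, -math.inf)
        logp[0] = 0.0
    else:
        _, logw = _support_and_logweights(table, math.log(psi))
        logp = logw - logsumexp(logw)
    karr = np.asarray(k)
    out = np.full(karr.shape, -math.inf, dtype=float)
    inside = (karr >= kmin) & (karr <= kmax)
    out[inside] = logp[karr[inside] - kmin]
    if np.isscalar(k) or karr.ndim == 0:
        return float(out)
    return out


def noncentral_hypergeom_pmf(
    k: int | np.ndarray, table: ContingencyTable, psi: float
) -> np.ndarray | float:
    return np.exp(noncentral_hypergeom_logpmf(k, table, psi))


def fisher_two_sided_p(table: ContingencyTable, rule: str = "minlike") -> float:
    """Two-sided exact test of psi = 1.

    ``rule="minlike"`` (default) sums the null probabilities of every
    outcome no more probable than the observed one -- the convention of
    standard exact-test implementations. ``rule="doubling"`` doubles the
    smaller tail, capped at 1.
    """
    k, logw = _support_and_logweights(table, 0.0)
    log_z = logsumexp(logw)
    idx = table.a - k[0]
    if not 0 <= idx < len(k):
        raise ValueError(f"observed cell {table.a} outside support {table.support()}")
    if rule == "minlike":
        mask = logw <= logw[idx] + math.log1p(_TIE_REL_TOL)
        p = math.exp(logsumexp(logw[mask]) - log_z)
    elif rule == "doubling":
        lower = math.exp(logsumexp(logw[: idx + 1]) - log_z)
        upper = math.exp(logsumexp(logw[idx:]) - log_z)
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown two-sided rule {rule!r}")
    # the exact p is strictly positive; guard against exp() underflow for
    # extreme tables (true p below ~1e-308)
    return min(1.0, max(p, 5e-324))


def _conditional_mean(table: ContingencyTable, log_psi: float) -> float:
    k, logw = _support_and_logweights(table, log_psi)
    w = np.exp(logw - logsumexp(logw))
    return float(np.dot(k, w))


def _bracket(f, lo: float, hi: float, limit: float = 500.0) -> tuple[float, float]:
    """Expand [lo, hi] geometrically until f changes sign across it."""
    flo, fhi = f(lo), f(hi)
    while flo * fhi > 0:
        if abs(lo) >= limit and abs(hi) >= limit:
            raise RuntimeError("root not bracketed within log-psi limits")
        lo, hi = lo * 2, hi * 2
        flo, fhi = f(lo), f(hi)
    return lo, hi


def conditional_mle_or(table: ContingencyTable, tol: float = 1e-10) -> float:
    """Conditional maximum-likelihood odds ratio.

    Solves ``E[K | psi] = a`` (the conditional score equation) by monotone
    root-finding on log psi. Returns +inf when the observed cell sits at
    the support maximum and 0 when it sits at the support minimum; for the
    degenerate zero-information table (empty support interior with a = 0,
    e.g. no alternate alleles anywhere) the conventional value 0 is
    returned.
    """
    kmin, kmax = table.support()
    if kmin == kmax:
        return math.inf if table.a > 0 else 0.0
    if table.a == kmax:
        return math.inf
    if table.a == kmin:
        return 0.0

    def score(log_psi: float) -> float:
        return _conditional_mean(table, log_psi) - table.a

    lo, hi = _bracket(score, -30.0, 30.0)
    log_psi = brentq(score, lo, hi, xtol=1e-12)
    assert abs(score(log_psi)) < max(tol, 1e-8 * table.a + tol)
    return math.exp(log_psi)


def exact_ci(table: ContingencyTable, alpha: float = 0.05) -> tuple[float, float]:
    """Exact confidence interval for the odds ratio by test inversion.

    The lower bound solves ``P(K >= a | psi) = alpha/2`` (0 when ``a`` is
    the support minimum) and the upper bound solves
    ``P(K <= a | psi) = alpha/2`` (+inf when ``a`` is the support maximum).
    Each root is found by bisection on log psi to 1e-8.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha outside (0, 1): {alpha}")
    kmin, kmax = table.support()
    a = table.a
    half = alpha / 2.0

    def tail(log_psi: float, upper_tail: bool) -> float:
        k, logw = _support_and_logweights(table, log_psi)
        log_z = logsumexp(logw)
        idx = a - kmin
        part = logw[idx:] if upper_tail else logw[: idx + 1]
        return math.exp(logsumexp(part) - log_z) - half

    if a == kmin:
        low = 0.0
    else:
        # P(K >= a | psi) is increasing in psi.
        f = lambda lp: tail(lp, upper_tail=True)
        lo, hi = _bracket(f, -30.0, 30.0)
        low = math.exp(brentq(f, lo, hi, xtol=1e-8))
    if a == kmax:
        high = math.inf
    else:
        f = lambda lp: tail(lp, upper_tail=False)
        lo, hi = _bracket(f, -30.0, 30.0)
        high = math.exp(brentq(f, lo, hi, xtol=1e-8))
    return low, high


def associate(
    case: CaseCohort | ControlFrequencyTable,
    control: ControlFrequencyTable,
    keys: Iterable[VariantKey],
    comparison: Comparison | None = None,
    *,
    compute_or: bool = True,
    alpha: float = 0.05,
    two_sided_rule: str = "minlike",
    genes: dict[VariantKey, str] | None = None,
) -> list[AssociationResult]:
    """Run the exact test for each key of one case-versus-control comparison.

    The case side may be a genotype-backed :class:`CaseCohort` or, for an
    external case cohort available only as aggregate frequencies, a
    :class:`ControlFrequencyTable`. Keys missing from the case side are
    reported ``untestable_case_absent``; keys the control panel does not
    report are ``untestable_control_absent`` (no table is formed -- absence
    from a panel is not a zero count). ``p_adjusted`` is left unset until
    multiple-testing adjustment runs.
    """
    comparison = comparison or Comparison(case.name, control.name)
    results: list[AssociationResult] = []
    for key in keys:
        gene = (genes or {}).get(key, "")
        if not case.has_variant(key):
            results.append(
                AssociationResult(
                    key, comparison, status=Status.UNTESTABLE_CASE_ABSENT, gene=gene
                )
            )
            continue
        if not control.present(key):
            results.append(
                AssociationResult(
                    key, comparison, status=Status.UNTESTABLE_CONTROL_ABSENT, gene=gene
                )
            )
            continue
        table = build_table(
            case.alt_allele_count(key),
            case.allele_number_at(key),
            control.frequency(key),
            control.allele_number_at(key),
        )
        res = AssociationResult(
            key,
            comparison,
            table=table,
            p_raw=fisher_two_sided_p(table, rule=two_sided_rule),
            gene=gene,
        )
        if compute_or:
            res.or_cmle = conditional_mle_or(table)
            res.or_sample = table.sample_odds_ratio()
            res.ci_low, res.ci_high = exact_ci(table, alpha=alpha)
        results.append(res)
    return results
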
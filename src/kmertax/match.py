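"""Exact best-match probabilities under uniform multiset k-mer sampling.

The similarity model: draw a uniform random multiset S_t of size t from the
|Q| k-mers of the query (all C(|Q|+t-1, t) multisets equiprobable). For a
reference whose k-mer set shares a = |Q ∩ K_i| k-mers with the query, the
number m of sampled k-mers that hit the shared pool follows the closed-form
PMF

    p_i(m) = C(a+m-1, m) · C(b+t-m-1, t-m) / C(|Q|+t-1, t),

the product of the multiset coefficients for choosing m from the matching
pool of size a and t-m from the non-matching pool of size b = |Q| - a. The
probability that reference i ties-or-beats every other candidate,

    P_i = Σ_{m≤t} p_i(m) · Π_{j≠i} CMF_j(m),

is evaluated in O(t) per reference by caching the all-candidate CMF product
C(m) = Π_j CMF_j(m) once and dividing out the candidate's own factor:
P_i = Σ_m p_i(m) · C(m) / CMF_i(m). C(m) is accumulated in log space so that
thousands of small CMF factors cannot underflow; the final L1 normalization
into confidence scores absorbs any common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .kmers import IntersectionCounts


class InvalidParameterError(ValueError):
    """Raised for inconsistent sampling parameters or intersection sizes."""


@dataclass(frozen=True)
class SamplingParameters:
    """Sample size t and the query's k-mer set size |Q|."""

    t: int = 32
    query_kmer_count: int = 1

    def __post_init__(self) -> None:
        if self.t < 1:
            raise InvalidParameterError(f"sample size t must be >= 1, got {self.t}")
        if self.query_kmer_count < 1:
            raise InvalidParameterError(
                f"query k-mer count must be >= 1, got {self.query_kmer_count}"
            )


@dataclass(frozen=True)
class MatchDistribution:
    """PMF and CMF of the number of matching sampled k-mers, m = 0..t."""

    pmf: np.ndarray
    cmf: np.ndarray


def _pmf_rows(
    a: np.ndarray, b: np.ndarray, t: int, q: int
) -> np.ndarray:
    """Vectorized PMF recurrence: one row per (a, b) pair, columns m = 0..t.

    Seeds p(0) = C(b+t-1, t) / C(q+t-1, t) as a running product of ratios and
    steps with p(m+1) = p(m) · (a+m)/(m+1) · (t-m)/(b+t-m-1) — one multiply
    and one divide per binomial coefficient per step, never factorials.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n = a.shape[0]
    pmf = np.zeros((n, t + 1), dtype=np.float64)
    # b = 0 means every query k-mer matches: all t draws match with certainty
    zero_b = b == 0
    p0 = np.ones(n, dtype=np.float64)
    for j in range(t):
        p0 *= (b + j) / (q + j)
    pmf[:, 0] = p0
    for m in range(t):
        denom = b + t - m - 1
        step = np.zeros(n, dtype=np.float64)
        ok = denom > 0
        step[ok] = (a[ok] + m) / (m + 1) * (t - m) / denom[ok]
        pmf[:, m + 1] = pmf[:, m] * step
    if zero_b.any():
        pmf[zero_b, :] = 0.0
        pmf[zero_b, t] = 1.0
    return pmf


def match_pmf(
    a: int,
    params: SamplingParameters,
    *,
    pool: str = "query",
    reference_kmer_count: int | None = None,
    exact: bool = False,
) -> MatchDistribution:
    """PMF/CMF of the match count for intersection size ``a``.

    ``pool`` selects the size of the non-matching pool in the second multiset
    coefficient: ``"query"`` (default) uses b = |Q| - a, under which the PMF
    sums to exactly 1; ``"reference"`` uses b = |K_i| - a and requires
    ``reference_kmer_count``. With ``exact=True`` the recurrence runs in
    rational arithmetic and the returned arrays hold :class:`~fractions.Fraction`
    objects (object dtype).
    """
    t, q = params.t, params.query_kmer_count
    if not 0 <= a <= q:
        raise InvalidParameterError(
            f"intersection size {a} outside [0, |Q|={q}]"
        )
    if pool == "query":
        b = q - a
    elif pool == "reference":
        if reference_kmer_count is None:
            raise InvalidParameterError(
                "pool='reference' requires reference_kmer_count"
            )
        if reference_kmer_count < a:
            raise InvalidParameterError(
                f"reference k-mer count {reference_kmer_count} < intersection {a}"
            )
        b = reference_kmer_count - a
    else:
        raise InvalidParameterError(f"unknown pmf pool {pool!r}")

    if exact:
        pmf = _pmf_exact(a, b, t, q)
        cmf = np.empty(t + 1, dtype=object)
        acc = Fraction(0)
        for m in range(t + 1):
            acc += pmf[m]
            cmf[m] = acc
        return MatchDistribution(pmf, cmf)

    pmf = _pmf_rows(np.array([a]), np.array([b]), t, q)[0]
    return MatchDistribution(pmf, np.cumsum(pmf))


def _pmf_exact(a: int, b: int, t: int, q: int) -> np.ndarray:
    """Rational-arithmetic version of the PMF recurrence (tests, small t)."""
    pmf = np.empty(t + 1, dtype=object)
    if b == 0:
        for m in range(t + 1):
            pmf[m] = Fraction(0)
        pmf[t] = Fraction(1)
        return pmf
    p = Fraction(1)
    for j in range(t):
        p *= Fraction(b + j, q + j)
    pmf[0] = p
    for m in range(t):
        pmf[m + 1] = pmf[m] * Fraction(a + m, m + 1) * Fraction(t - m, b + t - m - 1)
    return pmf


@dataclass(frozen=True)
class BestMatchProbabilities:
    """P_i per candidate reference plus the L1-normalized confidences."""

    indices: np.ndarray  # candidate reference leaf indices
    probs: np.ndarray  # P_i, aligned with indices
    confidence: np.ndarray  # probs / ||probs||_1


def _candidate_pmfs(
    intersections: IntersectionCounts,
    params: SamplingParameters,
    pool: str,
    reference_kmer_counts: np.ndarray | None,
) -> np.ndarray:
    t, q = params.t, params.query_kmer_count
    a = intersections.counts.astype(np.int64)
    if a.size and a.max() > q:
        raise InvalidParameterError("intersection size exceeds |Q|")
    if pool == "query":
        b = q - a
    elif pool == "reference":
        if reference_kmer_counts is None:
            raise InvalidParameterError("pool='reference' requires per-reference |K_i|")
        b = reference_kmer_counts[intersections.indices].astype(np.int64) - a
    else:
        raise InvalidParameterError(f"unknown pmf pool {pool!r}")
    return _pmf_rows(a, b, t, q)


def best_match_probabilities(
    intersections: IntersectionCounts,
    params: SamplingParameters,
    *,
    pool: str = "query",
    reference_kmer_counts: np.ndarray | None = None,
) -> BestMatchProbabilities | None:
    """Best-match probability P_i for every candidate reference.

    Candidates are the references with nonzero intersection; all others have
    CMF ≡ 1 and contribute a unit factor, so restricting to candidates is
    exact for the cached product and they are assigned P_i = 0 implicitly.
    Returns ``None`` (the unclassified signal) when there is no candidate.
    """
    if intersections.indices.size == 0:
        return None
    t = params.t
    pmfs = _candidate_pmfs(intersections, params, pool, reference_kmer_counts)
    cmfs = np.minimum(np.cumsum(pmfs, axis=1), 1.0)
    with np.errstate(divide="ignore"):
        log_cmfs = np.log(cmfs)  # -inf where CMF is 0
    log_c = log_cmfs.sum(axis=0)  # log C(m), -inf propagates exactly
    with np.errstate(invalid="ignore"):
        log_terms = log_c[None, :] - log_cmfs
    # p_i(m) = 0 forces the term to 0 (covers CMF_i(m) = 0, where p_i(m) = 0 too)
    terms = np.where(pmfs > 0.0, pmfs * np.exp(log_terms), 0.0)
    probs = terms.sum(axis=1)
    total = probs.sum()
    if total <= 0.0:
        raise ArithmeticError(
            "all best-match probabilities vanished; log-space accumulation "
            "should make this unreachable"
        )
    return BestMatchProbabilities(
        indices=intersections.indices.copy(),
        probs=probs,
        confidence=probs / total,
    )


def best_match_probabilities_naive(
    intersections: IntersectionCounts,
    params: SamplingParameters,
    *,
    pool: str = "query",
    reference_kmer_counts: np.ndarray | None = None,
) -> BestMatchProbabilities | None:
    """Direct O(n²t) evaluation of P_i = Σ_m p_i(m) Π_{j≠i} CMF_j(m).

    Test oracle for the cached fast path; use only on small instances.
    """
    if intersections.indices.size == 0:
        return None
    pmfs = _candidate_pmfs(intersections, params, pool, reference_kmer_counts)
    cmfs = np.minimum(np.cumsum(pmfs, axis=1), 1.0)
    n = pmfs.shape[0]
    probs = np.empty(n, dtype=np.float64)
    for i in range(n):
        others = np.prod(np.delete(cmfs, i, axis=0), axis=0) if n > 1 else np.ones_like(cmfs[0])
        probs[i] = float(np.sum(pmfs[i] * others))
    total = probs.sum()
    if total <= 0.0:
        raise ArithmeticError("all best-match probabilities vanished in naive path")
    return BestMatchProbabilities(
        indices=intersections.indices.copy(),
        probs=probs,
        confidence=probs / total,
    )
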
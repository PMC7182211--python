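"""Single-cell genotype likelihoods and maximum-likelihood calling.

The likelihood of a diploid genotype ``G = {A1, A2}`` given the read pileup
``D`` (M reads with observed bases b_i) is

    Pr(D | G) = prod_i [ 1/2 p(b_i | A1) + 1/2 p(b_i | A2) ],

with allelic dropout folded in as a three-component mixture

    Pr(D | G) = (1 - delta) * prod_i [ 1/2 p(b_i|A1) + 1/2 p(b_i|A2) ]
                + delta/2 * prod_i p(b_i|A1) + delta/2 * prod_i p(b_i|A2),

where delta is the per-site ADO probability.  The read-level term
``p(b | A)`` comes from one of three error models:

* **GATK-like** — sequencing error only: ``1 - eps`` if ``b == A``, else
  ``eps * e[A, b]`` (``eps/3`` with a uniform direction matrix);
* **four-template** — amplification error gamma mixed over all four
  possible templates, then sequencing error:
  ``p(b|A) = sum_j gamma_{A->t_j} eps_{t_j->b}``;
* **two-template** — a single wrong template:
  ``p(b|A) = sum_{j != A} e[A, t_j] ((1-gamma) eps_{A->b} + gamma eps_{t_j->b})``.

Reads are exchangeable, so all computations work from base counts.  Setting
``gamma = 0`` collapses both template models to the GATK model exactly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .readcounts import uniform_error_matrix, _validate_direction_matrix

__all__ = [
    "GENOTYPES_DNA",
    "GENOTYPES_BINARY",
    "genotype_pairs",
    "p_read_given_allele_gatk",
    "p_read_given_allele_four_template",
    "p_read_given_allele_two_template",
    "read_prob_matrix",
    "genotype_log_likelihood",
    "genotype_log_likelihood_ado",
    "genotype_log_likelihoods",
    "call_ml_genotype",
    "call_genotypes",
    "STATUS_CALLED",
    "STATUS_NO_COVERAGE",
    "STATUS_TIE",
]

#: Canonical unordered genotype orderings.
GENOTYPES_DNA = [
    (0, 0), (0, 1), (0, 2), (0, 3),
    (1, 1), (1, 2), (1, 3),
    (2, 2), (2, 3), (3, 3),
]
GENOTYPES_BINARY = [(0, 0), (0, 1), (1, 1)]

STATUS_CALLED = 0
STATUS_NO_COVERAGE = 1
STATUS_TIE = 2

_PROB_FLOOR = 1e-300  # keeps logs finite when eps/gamma are exactly 0
_TIE_ATOL = 1e-9


def genotype_pairs(k: int = 4) -> list[tuple[int, int]]:
    return GENOTYPES_DNA if k == 4 else GENOTYPES_BINARY


def _e_or_uniform(e, k: int) -> np.ndarray:
    if e is None:
        return uniform_error_matrix(k)
    return _validate_direction_matrix(np.asarray(e, dtype=float), k)


# ---------------------------------------------------------------------------
# Read-level error models: p(b | A)
# ---------------------------------------------------------------------------


def p_read_given_allele_gatk(b: int, A: int, eps: float, e=None, k: int = 4) -> float:
    """Sequencing-error-only model: 1 - eps on the true allele, eps*e off it."""
    e = _e_or_uniform(e, k)
    if b == A:
        return 1.0 - eps
    return eps * float(e[A, b])


def p_read_given_allele_four_template(
    b: int, A: int, gamma: float, eps: float, e=None, k: int = 4
) -> float:
    """Mixture over all possible amplified templates.

    ``p(b|A) = sum_j gamma_{A->t_j} eps_{t_j->b}`` with
    ``gamma_{i->j} = gamma e[i,j]`` off-diagonal and ``1 - gamma`` on it (and
    analogously for eps); multiple amplification errors can occur, so all
    template bases are possible.
    """
    e = _e_or_uniform(e, k)
    total = 0.0
    for t in range(k):
        g = (1.0 - gamma) if t == A else gamma * float(e[A, t])
        s = (1.0 - eps) if b == t else eps * float(e[t, b])
        total += g * s
    return total


def p_read_given_allele_two_template(
    b: int, A: int, gamma: float, eps: float, e=None, k: int = 4
) -> float:
    """Single-wrong-template model.

    ``p(b|A) = sum_{j != A} e[A, t_j] [ (1-gamma) eps_{A->b} + gamma eps_{t_j->b} ]``:
    a fraction gamma of the template pool is one wrong base drawn from the
    direction matrix.
    """
    e = _e_or_uniform(e, k)
    eps_ab = (1.0 - eps) if b == A else eps * float(e[A, b])
    total = 0.0
    for t in range(k):
        if t == A:
            continue
        eps_tb = (1.0 - eps) if b == t else eps * float(e[t, b])
        total += float(e[A, t]) * ((1.0 - gamma) * eps_ab + gamma * eps_tb)
    return total


def read_prob_matrix(
    model: str,
    eps: float,
    gamma: float = 0.0,
    e_amp=None,
    e_seq=None,
    k: int = 4,
) -> np.ndarray:
    """Matrix ``P[A, b] = p(read base b | true allele A)`` for one error model.

    ``model`` is one of ``'gatk'``, ``'four_template'``, ``'two_template'``.
    Every row sums to 1.
    """
    funcs = {
        "gatk": lambda b, A: p_read_given_allele_gatk(b, A, eps, e_seq, k),
        "four_template": lambda b, A: _four_template_entry(
            b, A, gamma, eps, e_amp, e_seq, k
        ),
        "two_template": lambda b, A: _two_template_entry(
            b, A, gamma, eps, e_amp, e_seq, k
        ),
    }
    if model not in funcs:
        raise ValueError(f"unknown likelihood model {model!r}")
    f = funcs[model]
    return np.array([[f(b, A) for b in range(k)] for A in range(k)])


def _four_template_entry(b, A, gamma, eps, e_amp, e_seq, k):
    ea = _e_or_uniform(e_amp, k)
    es = _e_or_uniform(e_seq, k)
    total = 0.0
    for t in range(k):
        g = (1.0 - gamma) if t == A else gamma * float(ea[A, t])
        s = (1.0 - eps) if b == t else eps * float(es[t, b])
        total += g * s
    return total


def _two_template_entry(b, A, gamma, eps, e_amp, e_seq, k):
    ea = _e_or_uniform(e_amp, k)
    es = _e_or_uniform(e_seq, k)
    eps_ab = (1.0 - eps) if b == A else eps * float(es[A, b])
    total = 0.0
    for t in range(k):
        if t == A:
            continue
        eps_tb = (1.0 - eps) if b == t else eps * float(es[t, b])
        total += float(ea[A, t]) * ((1.0 - gamma) * eps_ab + gamma * eps_tb)
    return total


# ---------------------------------------------------------------------------
# Genotype likelihoods
# ---------------------------------------------------------------------------


def genotype_log_likelihood(
    base_counts: np.ndarray, genotype: tuple[int, int], prob_matrix: np.ndarray
) -> float:
    """log Pr(D | G) from base counts (reads are exchangeable).

    ``sum_b n_b log( 1/2 p(b|A1) + 1/2 p(b|A2) )``; 0 for an empty pileup.
    """
    counts = np.asarray(base_counts, dtype=float)
    a1, a2 = genotype
    p = 0.5 * prob_matrix[a1] + 0.5 * prob_matrix[a2]
    return float(np.dot(counts, np.log(np.maximum(p, _PROB_FLOOR))))


def genotype_log_likelihood_ado(
    base_counts: np.ndarray,
    genotype: tuple[int, int],
    delta: float,
    prob_matrix: np.ndarray,
) -> float:
    """ADO-mixture log-likelihood.

    ``(1-delta) * diploid + delta/2 * haploid(A1) + delta/2 * haploid(A2)``,
    evaluated in log space; collapses to the plain likelihood at delta=0 and
    to the average of the haploid likelihoods at delta=1.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0,1], got {delta}")
    counts = np.asarray(base_counts, dtype=float)
    a1, a2 = genotype
    logp = np.log(np.maximum(prob_matrix, _PROB_FLOOR))
    hap1 = float(np.dot(counts, logp[a1]))
    hap2 = float(np.dot(counts, logp[a2]))
    dip = genotype_log_likelihood(counts, genotype, prob_matrix)
    if delta == 0.0:
        return dip
    if delta == 1.0:
        return float(logsumexp([hap1, hap2], b=[0.5, 0.5]))
    return float(
        logsumexp(
            [dip, hap1, hap2], b=[1.0 - delta, delta / 2.0, delta / 2.0]
        )
    )


def genotype_log_likelihoods(
    base_counts: np.ndarray,
    prob_matrix: np.ndarray,
    delta: Optional[float] = None,
) -> np.ndarray:
    """Vectorized log-likelihood over all unordered genotypes.

    ``base_counts`` has shape ``(..., k)``; returns ``(..., n_genotypes)``
    following :data:`GENOTYPES_DNA` / :data:`GENOTYPES_BINARY` order.
    """
    counts = np.asarray(base_counts, dtype=float)
    k = prob_matrix.shape[0]
    pairs = genotype_pairs(k)
    logp = np.log(np.maximum(prob_matrix, _PROB_FLOOR))  # (k, k)
    hap = counts @ logp.T  # (..., k): log prod p(b|A)^n_b
    pg = np.stack(
        [0.5 * prob_matrix[a1] + 0.5 * prob_matrix[a2] for a1, a2 in pairs]
    )  # (G, k)
    dip = counts @ np.log(np.maximum(pg, _PROB_FLOOR)).T  # (..., G)
    if delta is None or delta == 0.0:
        return dip
    a1 = np.array([p[0] for p in pairs])
    a2 = np.array([p[1] for p in pairs])
    stack = np.stack([dip, hap[..., a1], hap[..., a2]], axis=0)
    if delta == 1.0:
        weights = np.array([0.0, 0.5, 0.5])
        stack = stack[1:]
        weights = weights[1:]
    else:
        weights = np.array([1.0 - delta, delta / 2.0, delta / 2.0])
    shape = (stack.shape[0],) + (1,) * (stack.ndim - 1)
    return logsumexp(stack, axis=0, b=weights.reshape(shape))


# ---------------------------------------------------------------------------
# ML calling
# ---------------------------------------------------------------------------


def call_genotypes(
    base_counts: np.ndarray,
    prob_matrix: np.ndarray,
    delta: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Maximum-likelihood genotype per pileup, with a call status.

    Returns ``(allele1, allele2, status, loglik)`` where status is
    ``STATUS_CALLED``, ``STATUS_NO_COVERAGE`` (M = 0) or ``STATUS_TIE`` (the
    maximum is shared by genotypes with different allele content, which are
    reported as no-calls so downstream error metrics cannot depend on
    enumeration order).  Alleles are -9 where there is no call.
    """
    counts = np.asarray(base_counts)
    k = prob_matrix.shape[0]
    pairs = genotype_pairs(k)
    ll = genotype_log_likelihoods(counts, prob_matrix, delta)
    best = np.argmax(ll, axis=-1)
    maxll = np.take_along_axis(ll, best[..., None], axis=-1)[..., 0]
    n_at_max = np.sum(np.isclose(ll, maxll[..., None], rtol=0.0, atol=_TIE_ATOL), axis=-1)
    m = counts.sum(axis=-1)
    status = np.full(best.shape, STATUS_CALLED, dtype=np.int8)
    status[n_at_max > 1] = STATUS_TIE
    status[m == 0] = STATUS_NO_COVERAGE
    a1 = np.array([p[0] for p in pairs], dtype=np.int8)[best]
    a2 = np.array([p[1] for p in pairs], dtype=np.int8)[best]
    nocall = status != STATUS_CALLED
    a1 = np.where(nocall, np.int8(-9), a1)
    a2 = np.where(nocall, np.int8(-9), a2)
    return a1, a2, status, ll


def call_ml_genotype(
    base_counts: np.ndarray,
    prob_matrix: np.ndarray,
    delta: Optional[float] = None,
) -> tuple[Optional[tuple[int, int]], int]:
    """Single-pileup convenience wrapper around :func:`call_genotypes`."""
    a1, a2, status, _ = call_genotypes(
        np.asarray(base_counts)[None, :], prob_matrix, delta
    )
    if status[0] != STATUS_CALLED:
        return None, int(status[0])
    return (int(a1[0]), int(a2[0])), STATUS_CALLED
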
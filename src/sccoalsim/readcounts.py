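"""Single-cell sequencing noise: from true genotypes to read counts.

Models the main artifacts of single-cell whole-genome amplification (scWGA)
and sequencing:

* **ADO** — each allele of each cell/site fails to amplify with probability
  delta, optionally varying across cells and/or sites via a beta
  distribution parameterized by mean and variance;
* **coverage** — Poisson or negative-binomial total depth per cell/site,
  with a configurable reduction (default 50%) at sites where only one
  allele remains (by dropout or deletion);
* **allelic imbalance** — reads split between the surviving alleles by a
  beta-binomial (maternal proportion drawn from a beta), conditioned on the
  ADO status;
* **amplification error** — a per-site error probability gamma drawn from a
  beta, propagated through the template pool under either a four-template
  model (multiple amplification errors possible, all four bases can appear
  as templates) or a two-template model (a single wrong template per site);
* **sequencing error** — per-read misreads at rate epsilon with a
  direction matrix;
* **doublets** — a cell's library is mixed with a uniformly chosen partner
  cell, reassigning reads according to a beta-binomial while keeping the
  original depth.

Alternatively, genotype errors can be imposed directly on the evolved
genotypes, encapsulating the whole pipeline's error into a single class.

Read counts are independent across sites; coverage correlation along the
genome is deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mutation import DEL

__all__ = [
    "ADOModel",
    "CoverageModel",
    "AllelicImbalanceModel",
    "AmplificationErrorModel",
    "SequencingErrorModel",
    "NoiseConfig",
    "Pileups",
    "beta_params_from_mean_var",
    "sample_ado_status",
    "sample_coverage",
    "partition_reads",
    "sample_read_base",
    "generate_pileups",
    "make_doublets",
    "impose_direct_genotype_errors",
    "uniform_error_matrix",
]


def beta_params_from_mean_var(mean: float, var: float) -> tuple[float, float]:
    """Convert a (mean, variance) pair to beta shape parameters.

    Requires ``0 < mean < 1`` and ``0 <= var < mean (1 - mean)``; ``var = 0``
    is handled by callers as a degenerate (constant) distribution.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mean}")
    if var < 0 or var >= mean * (1.0 - mean):
        raise ValueError(
            f"beta variance must satisfy 0 <= var < mean(1-mean); "
            f"got mean={mean}, var={var}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _draw_beta(
    mean: float, var: float, size, rng: np.random.Generator
) -> np.ndarray:
    if var == 0.0:
        return np.full(size, mean)
    a, b = beta_params_from_mean_var(mean, var)
    return rng.beta(a, b, size=size)


def uniform_error_matrix(k: int = 4) -> np.ndarray:
    """Row-normalized direction matrix with equal off-diagonal mass."""
    e = (np.ones((k, k)) - np.eye(k)) / (k - 1)
    return e


def _validate_direction_matrix(e: np.ndarray, k: int) -> np.ndarray:
    e = np.asarray(e, dtype=float)
    if e.shape != (k, k):
        raise ValueError(f"direction matrix must be {k}x{k}")
    if np.any(e < 0) or np.any(np.diag(e) != 0):
        raise ValueError("direction matrix needs nonnegative entries, zero diagonal")
    rows = e.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-8):
        raise ValueError("direction matrix rows must sum to 1 over off-diagonals")
    return e / rows[:, None]


# ---------------------------------------------------------------------------
# Model dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ADOModel:
    """Allelic dropout: each allele amplifies with probability 1 - delta."""

    delta: float = 0.0
    variation: str = "fixed"  # fixed | per_cell | per_site | per_cell_and_site
    beta_var: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"ADO delta must be in [0,1], got {self.delta}")
        if self.variation not in ("fixed", "per_cell", "per_site", "per_cell_and_site"):
            raise ValueError(f"unknown ADO variation mode {self.variation!r}")
        if self.variation != "fixed" and self.beta_var > 0:
            beta_params_from_mean_var(self.delta, self.beta_var)  # validates


@dataclass
class CoverageModel:
    """Total depth per cell/site: NB(mean, dispersion); dispersion=inf -> Poisson."""

    mean: float = 0.0
    dispersion: float = math.inf
    haploid_reduction: float = 0.5  # coverage factor at single-allele sites

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("coverage mean must be nonnegative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (inf for Poisson)")
        if not 0.0 <= self.haploid_reduction <= 1.0:
            raise ValueError("haploid_reduction must be in [0,1]")


@dataclass
class AllelicImbalanceModel:
    """Maternal read proportion ~ Beta(mean, var); var=0 -> exact Binomial(0.5)."""

    beta_mean: float = 0.5
    beta_var: float = 0.0

    def __post_init__(self) -> None:
        if self.beta_var > 0:
            beta_params_from_mean_var(self.beta_mean, self.beta_var)


@dataclass
class AmplificationErrorModel:
    """scWGA polymerase error entering the template pool.

    ``gamma`` for each cell/site is drawn from a beta with the given mean and
    variance and shared by all of that site's reads (the error propagates
    through the amplified templates).  ``four_template`` allows multiple
    amplification errors per site; ``two_template`` allows a single wrong
    template whose identity is drawn once per cell/site/allele.
    """

    gamma_mean: float = 0.0
    gamma_var: float = 0.0
    direction_matrix: Optional[np.ndarray] = None
    template_mode: str = "four_template"  # four_template | two_template

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_mean <= 1.0:
            raise ValueError("gamma mean must be in [0,1]")
        if self.gamma_var > 0:
            beta_params_from_mean_var(self.gamma_mean, self.gamma_var)
        if self.template_mode not in ("four_template", "two_template"):
            raise ValueError(f"unknown template mode {self.template_mode!r}")


@dataclass
class SequencingErrorModel:
    """Per-read sequencing error at rate epsilon with a direction matrix."""

    epsilon: float = 0.0
    direction_matrix: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0,1]")


@dataclass
class NoiseConfig:
    """All single-cell noise settings for read-count generation."""

    ado: ADOModel = field(default_factory=ADOModel)
    coverage: CoverageModel = field(default_factory=CoverageModel)
    allelic_imbalance: AllelicImbalanceModel = field(
        default_factory=AllelicImbalanceModel
    )
    amplification: Optional[AmplificationErrorModel] = None
    sequencing: SequencingErrorModel = field(default_factory=SequencingErrorModel)
    doublet_rate: float = 0.0
    doublet_mix_mean: float = 0.5
    doublet_mix_var: float = 0.0
    n_states: int = 4  # 2 for the binary alphabet

    def __post_init__(self) -> None:
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet rate must be in [0,1]")
        if self.doublet_mix_var > 0:
            beta_params_from_mean_var(self.doublet_mix_mean, self.doublet_mix_var)


@dataclass
class Pileups:
    """Observed read counts per cell x site.

    ``counts[c, s, b]`` is the number of reads of base ``b``; ``dp`` the total
    depth M (always the base-count sum); ADO and doublet flags record the
    simulation truth.
    """

    counts: np.ndarray  # (n_cells, l, k) int64
    dp: np.ndarray  # (n_cells, l)
    ado_maternal: np.ndarray  # (n_cells, l) bool
    ado_paternal: np.ndarray
    doublet: np.ndarray  # (n_cells,) bool
    doublet_partner: np.ndarray  # (n_cells,) int, -1 if not a doublet


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------


def sample_ado_status(
    n_cells: int, l: int, model: ADOModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dropout flags for the maternal and paternal allele of each cell/site."""
    if model.variation == "fixed" or model.beta_var == 0.0:
        delta = np.full((n_cells, l), model.delta)
    elif model.variation == "per_cell":
        delta = np.broadcast_to(
            _draw_beta(model.delta, model.beta_var, (n_cells, 1), rng), (n_cells, l)
        )
    elif model.variation == "per_site":
        delta = np.broadcast_to(
            _draw_beta(model.delta, model.beta_var, (1, l), rng), (n_cells, l)
        )
    else:  # per_cell_and_site
        delta = _draw_beta(model.delta, model.beta_var, (n_cells, l), rng)
    ado_m = rng.random((n_cells, l)) < delta
    ado_p = rng.random((n_cells, l)) < delta
    return ado_m, ado_p


def sample_coverage(
    model: CoverageModel, n_alleles: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Total depth given the number of amplifiable alleles (0, 1 or 2).

    Sites with one surviving allele get their mean multiplied by the haploid
    reduction factor; sites with no surviving allele get depth 0.
    """
    n_alleles = np.asarray(n_alleles)
    mean = np.where(
        n_alleles == 2,
        model.mean,
        np.where(n_alleles == 1, model.mean * model.haploid_reduction, 0.0),
    )
    if math.isinf(model.dispersion):
        return rng.poisson(mean)
    r = model.dispersion
    p = r / (r + np.maximum(mean, 1e-300))
    cov = rng.negative_binomial(r, p)
    return np.where(mean > 0, cov, 0)


def partition_reads(
    coverage: np.ndarray,
    ai: AllelicImbalanceModel,
    maternal_present: np.ndarray,
    paternal_present: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Split depth between maternal and paternal templates.

    With both alleles present the maternal proportion is a beta draw (exact
    binomial split when the beta is degenerate); with a single allele all
    reads come from it — always conditioned on the ADO/deletion status.
    """
    coverage = np.asarray(coverage)
    p = _draw_beta(ai.beta_mean, ai.beta_var, coverage.shape, rng)
    both = maternal_present & paternal_present
    m_reads = np.where(
        both,
        rng.binomial(coverage, p),
        np.where(maternal_present, coverage, 0),
    )
    return m_reads, coverage - m_reads


def _gamma_mix_rows(
    allele: np.ndarray, gamma: np.ndarray, e: np.ndarray
) -> np.ndarray:
    """Template distribution rows: gamma*e off the true allele, 1-gamma on it."""
    rows = gamma[..., None] * e[allele]
    np.put_along_axis(rows, allele[..., None], 1.0 - gamma[..., None], axis=-1)
    return rows


def _eps_mix_matrix(epsilon: float, e: np.ndarray) -> np.ndarray:
    k = e.shape[0]
    m = epsilon * e
    m[np.arange(k), np.arange(k)] = 1.0 - epsilon
    return m


def sample_read_base(
    true_allele: int,
    gamma_site: float,
    amp: Optional[AmplificationErrorModel],
    seq: SequencingErrorModel,
    rng: np.random.Generator,
    k: int = 4,
) -> int:
    """Draw a single observed read base given the template's true allele.

    Four-template mode first draws the amplified template from the
    gamma-mixture over all bases, then the read from the epsilon-mixture; in
    two-template mode a single wrong template is drawn from the direction
    matrix and supplies a fraction gamma of the templates.
    """
    e_amp = (
        _validate_direction_matrix(
            amp.direction_matrix
            if amp is not None and amp.direction_matrix is not None
            else uniform_error_matrix(k),
            k,
        )
    )
    e_seq = _validate_direction_matrix(
        seq.direction_matrix if seq.direction_matrix is not None else uniform_error_matrix(k),
        k,
    )
    eps_rows = _eps_mix_matrix(seq.epsilon, e_seq)
    if amp is None or gamma_site == 0.0:
        template = true_allele
    elif amp.template_mode == "four_template":
        row = gamma_site * e_amp[true_allele]
        row[true_allele] = 1.0 - gamma_site
        template = int(rng.choice(k, p=row))
    else:
        wrong = int(rng.choice(k, p=e_amp[true_allele]))
        template = wrong if rng.random() < gamma_site else true_allele
    return int(rng.choice(k, p=eps_rows[template]))


def _reads_to_bases(
    n_reads: np.ndarray,
    allele: np.ndarray,
    gamma: np.ndarray,
    amp: Optional[AmplificationErrorModel],
    seq: SequencingErrorModel,
    rng: np.random.Generator,
    k: int,
) -> np.ndarray:
    """Observed base counts for ``n_reads`` templates of a given allele.

    Vectorized over (cell, site); deleted/absent alleles must come in with
    zero reads.
    """
    shape = n_reads.shape
    counts = np.zeros(shape + (k,), dtype=np.int64)
    alle = np.clip(allele, 0, k - 1).astype(np.intp)  # DEL rows carry 0 reads
    e_seq = _validate_direction_matrix(
        seq.direction_matrix if seq.direction_matrix is not None else uniform_error_matrix(k),
        k,
    )
    eps_rows = _eps_mix_matrix(seq.epsilon, e_seq)
    no_amp = amp is None or (np.all(gamma == 0.0))
    if no_amp and seq.epsilon == 0.0:
        np.put_along_axis(counts, alle[..., None], n_reads[..., None], axis=-1)
        return counts
    e_amp = _validate_direction_matrix(
        amp.direction_matrix
        if amp is not None and amp.direction_matrix is not None
        else uniform_error_matrix(k),
        k,
    )
    if no_amp:
        templates = np.zeros(shape + (k,), dtype=np.int64)
        np.put_along_axis(templates, alle[..., None], n_reads[..., None], axis=-1)
    elif amp.template_mode == "four_template":
        rows = _gamma_mix_rows(alle, gamma, e_amp)
        rows /= rows.sum(axis=-1, keepdims=True)
        templates = rng.multinomial(n_reads, rows)
    else:  # two_template: one wrong template per cell/site/allele
        wrong_rows = e_amp[alle]
        u = rng.random(shape)
        wrong = (u[..., None] > np.cumsum(wrong_rows, axis=-1)).sum(axis=-1)
        n_wrong = rng.binomial(n_reads, gamma)
        templates = np.zeros(shape + (k,), dtype=np.int64)
        np.put_along_axis(templates, alle[..., None], (n_reads - n_wrong)[..., None], -1)
        wrong_oh = np.zeros(shape + (k,), dtype=np.int64)
        np.put_along_axis(wrong_oh, wrong[..., None], n_wrong[..., None], -1)
        templates += wrong_oh
    if seq.epsilon == 0.0:
        return templates
    for t in range(k):
        counts += rng.multinomial(templates[..., t], eps_rows[t])
    return counts


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def generate_pileups(
    maternal: np.ndarray,
    paternal: np.ndarray,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> Pileups:
    """Simulate read counts for every cell x site.

    Composes ADO sampling, depth sampling, allelic partitioning, and
    amplification/sequencing error; a per-site amplification error
    probability gamma is drawn once per cell/site and shared by that site's
    reads.  Doublets, if enabled, are applied last.
    """
    maternal = np.asarray(maternal)
    paternal = np.asarray(paternal)
    n_cells, l = maternal.shape
    k = noise.n_states
    ado_m, ado_p = sample_ado_status(n_cells, l, noise.ado, rng)
    present_m = (maternal != DEL) & ~ado_m
    present_p = (paternal != DEL) & ~ado_p
    # dropout of a deleted allele is meaningless; keep flags only where real
    ado_m &= maternal != DEL
    ado_p &= paternal != DEL
    n_alleles = present_m.astype(int) + present_p.astype(int)
    cov = sample_coverage(noise.coverage, n_alleles, rng)
    m_reads, p_reads = partition_reads(
        cov, noise.allelic_imbalance, present_m, present_p, rng
    )
    amp = noise.amplification
    if amp is not None and amp.gamma_mean > 0:
        gamma = _draw_beta(amp.gamma_mean, amp.gamma_var, (n_cells, l), rng)
    else:
        gamma = np.zeros((n_cells, l))
    counts = _reads_to_bases(m_reads, maternal, gamma, amp, noise.sequencing, rng, k)
    counts += _reads_to_bases(p_reads, paternal, gamma, amp, noise.sequencing, rng, k)
    pile = Pileups(
        counts=counts,
        dp=counts.sum(axis=-1),
        ado_maternal=ado_m,
        ado_paternal=ado_p,
        doublet=np.zeros(n_cells, dtype=bool),
        doublet_partner=np.full(n_cells, -1, dtype=int),
    )
    if noise.doublet_rate > 0:
        pile = make_doublets(
            pile, noise.doublet_rate, noise.doublet_mix_mean, noise.doublet_mix_var, rng
        )
    return pile


def make_doublets(
    pileups: Pileups,
    doublet_rate: float,
    mix_mean: float,
    mix_var: float,
    rng: np.random.Generator,
) -> Pileups:
    """Mix read counts of doublet cells with a random partner cell.

    Each cell is flagged a doublet with probability ``doublet_rate``; a
    partner is chosen uniformly among the other cells (with replacement
    across doublets).  At each site the cell keeps its own total depth: each
    read stays its own with probability ``p ~ Beta(mix_mean, mix_var)`` and
    is otherwise redrawn from the partner's site-specific base distribution.
    """
    if not 0.0 <= doublet_rate <= 1.0:
        raise ValueError("doublet rate must be in [0,1]")
    n_cells, l, k = pileups.counts.shape
    if n_cells < 2 and doublet_rate > 0:
        raise ValueError("doublets require at least two cells")
    counts = pileups.counts.copy()
    flags = rng.random(n_cells) < doublet_rate
    partners = np.full(n_cells, -1, dtype=int)
    for c in np.flatnonzero(flags):
        q = int(rng.integers(n_cells - 1))
        if q >= c:
            q += 1
        partners[c] = q
        p_keep = _draw_beta(mix_mean, mix_var, l, rng)
        own = pileups.counts[c]
        partner = pileups.counts[q]
        partner_m = partner.sum(axis=-1)
        for s in range(l):
            m = int(own[s].sum())
            if m == 0 or partner_m[s] == 0:
                continue
            keep = int(rng.binomial(m, p_keep[s]))
            kept = rng.multivariate_hypergeometric(own[s], keep)
            swapped = rng.multinomial(m - keep, partner[s] / partner_m[s])
            counts[c, s] = kept + swapped
    return Pileups(
        counts=counts,
        dp=counts.sum(axis=-1),
        ado_maternal=pileups.ado_maternal,
        ado_paternal=pileups.ado_paternal,
        doublet=flags,
        doublet_partner=partners,
    )


def impose_direct_genotype_errors(
    maternal: np.ndarray,
    paternal: np.ndarray,
    rate: float,
    error_matrix: Optional[np.ndarray],
    rng: np.random.Generator,
    k: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace each (non-deleted) allele with probability ``rate``.

    The replacement allele follows the row-normalized error matrix; this
    encapsulates amplification, sequencing and calling errors into a single
    class acting directly on the genotypes.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"error rate must be in [0,1], got {rate}")
    e = _validate_direction_matrix(
        error_matrix if error_matrix is not None else uniform_error_matrix(k), k
    )
    cum = np.cumsum(e, axis=1)
    out = []
    for hap in (np.asarray(maternal), np.asarray(paternal)):
        new = hap.copy()
        hit = (rng.random(hap.shape) < rate) & (hap != DEL)
        idx = np.flatnonzero(hit.ravel())
        if idx.size:
            flat = new.ravel()
            u = rng.random(idx.size)
            rows = cum[flat[idx].astype(np.intp)]
            flat[idx] = (u[:, None] > rows).sum(axis=1)
        out.append(new)
    return out[0], out[1]
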
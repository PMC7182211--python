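"""Somatic genotype evolution along a cell genealogy.

Diploid genotypes (an unordered maternal/paternal allele pair per site) start
from an ancestral genome at the tree root — homozygous unless germline
variants are added — and evolve by:

* **SNVs** under a diploid infinite-site model (ISM; at most one mutation per
  site, hitting one haplotype), a trinucleotide mutational-signature model
  (96 substitution channels in pyrimidine-strand convention), or finite-site
  substitution models (FSM: the binary Mk2/CFN model, JC, HKY, GTR and a
  fully nonreversible 12-parameter model), optionally with gamma rate
  variation among sites;
* **cnLOH** events (one parental allele overwritten by the other, haploid
  ISM: a (site, haplotype) pair is hit at most once);
* **point deletions** (an allele replaced by the deleted marker, haploid
  ISM); deleted alleles produce no sequencing reads downstream.

Branch lengths are in coalescent units (see :mod:`sccoalsim.genealogy`); the
number of SNVs is either fixed (multinomial allocation proportional to branch
lengths) or Poisson with a genome-wide rate per unit branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space

from .genealogy import LABEL_OUTGROUP, CellGenealogy, TreeNode

__all__ = [
    "DEL",
    "DNA",
    "Genotype",
    "SubstitutionModel",
    "AncestralGenome",
    "MutationEvent",
    "ISMExhaustedError",
    "generate_ancestral_genome",
    "load_ancestral_genome_fasta",
    "add_germline_variants",
    "place_mutations_on_branches",
    "evolve_ism_diploid",
    "evolve_signature_mutations",
    "evolve_fsm_along_tree",
    "evolve_genotypes",
    "apply_cnloh",
    "apply_deletions",
    "fsm_transition_matrix",
    "load_signature_catalogue",
    "signature_channels",
    "expected_segregating_sites",
]

DNA = "ACGT"
DEL = -1  # deleted-allele marker in genotype matrices
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G
_PYRIMIDINES = (1, 3)  # C, T


class ISMExhaustedError(RuntimeError):
    """More infinite-site events requested than available (site, haplotype) slots."""


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of maternal/paternal alleles at one site."""

    maternal: int
    paternal: int

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return {self.maternal, self.paternal} == {other.maternal, other.paternal} and (
            sorted((self.maternal, self.paternal))
            == sorted((other.maternal, other.paternal))
        )

    def __hash__(self) -> int:
        return hash(tuple(sorted((self.maternal, self.paternal))))


@dataclass
class MutationEvent:
    """One somatic event on a branch of the genealogy."""

    node_id: int
    site: int
    haplotype: int  # 0 = maternal, 1 = paternal
    kind: str  # 'SNV' | 'cnLOH' | 'deletion'
    from_allele: Optional[int] = None
    to_allele: Optional[int] = None
    channel: Optional[int] = None  # signature channel index, SNVs only
    germline_site: bool = False  # SNV placed on a site already heterozygous


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionModel:
    """Mutation-model specification.

    ``relative_rates`` is a k×k nonnegative matrix with zero diagonal: for
    reversible FSMs the GTR exchange terms (``q_ij = r_ij * pi_j``), for the
    nonreversible FSM the instantaneous rates themselves, and for ISM the
    relative probabilities of the derived allele given the ancestral one.
    """

    alphabet: str = "DNA"  # 'DNA' | 'binary'
    family: str = "ISM_diploid"  # 'ISM_diploid' | 'trinuc_signature' | 'FSM'
    base_freqs: Optional[np.ndarray] = None
    relative_rates: Optional[np.ndarray] = None
    gamma_site_alpha: Optional[float] = None
    signature: Optional[np.ndarray] = None
    fixed_mutations: Optional[int] = None
    mutation_rate: Optional[float] = None
    reversible: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        k = self.n_states
        if self.base_freqs is None:
            self.base_freqs = np.full(k, 1.0 / k)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.base_freqs.shape != (k,):
            raise ValueError(f"base_freqs must have length {k}")
        if np.any(self.base_freqs < 0) or not math.isclose(
            self.base_freqs.sum(), 1.0, abs_tol=1e-8
        ):
            raise ValueError("base_freqs must be a probability simplex")
        if self.relative_rates is None:
            self.relative_rates = np.ones((k, k)) - np.eye(k)
        self.relative_rates = np.asarray(self.relative_rates, dtype=float)
        if self.relative_rates.shape != (k, k):
            raise ValueError(f"relative_rates must be {k}x{k}")
        if np.any(self.relative_rates < 0):
            raise ValueError("relative_rates must be nonnegative")
        if np.any(np.diag(self.relative_rates) != 0):
            raise ValueError("relative_rates diagonal must be zero")
        if self.gamma_site_alpha is not None and self.gamma_site_alpha <= 0:
            raise ValueError("gamma_site_alpha must be positive")
        if self.signature is not None:
            self.signature = np.asarray(self.signature, dtype=float)
            if self.signature.shape != (96,):
                raise ValueError("signature must have 96 channels")
            if not math.isclose(self.signature.sum(), 1.0, abs_tol=1e-6):
                raise ValueError("signature channels must sum to 1")
        if self.fixed_mutations is not None and self.fixed_mutations < 0:
            raise ValueError("fixed_mutations must be nonnegative")
        if self.mutation_rate is not None and self.mutation_rate < 0:
            raise ValueError("mutation_rate must be nonnegative")

    @property
    def n_states(self) -> int:
        return 4 if self.alphabet == "DNA" else 2

    # -- named constructors ------------------------------------------------

    @classmethod
    def jc(cls, **kw) -> "SubstitutionModel":
        return cls(alphabet="DNA", family="FSM", name="JC", **kw)

    @classmethod
    def hky(cls, kappa: float, base_freqs, **kw) -> "SubstitutionModel":
        r = np.ones((4, 4)) - np.eye(4)
        r[0, 2] = r[2, 0] = kappa  # A<->G transitions
        r[1, 3] = r[3, 1] = kappa  # C<->T transitions
        return cls(
            alphabet="DNA",
            family="FSM",
            base_freqs=base_freqs,
            relative_rates=r,
            name="HKY",
            **kw,
        )

    @classmethod
    def gtr(cls, relative_rates, base_freqs, **kw) -> "SubstitutionModel":
        return cls(
            alphabet="DNA",
            family="FSM",
            base_freqs=base_freqs,
            relative_rates=relative_rates,
            name="GTR",
            **kw,
        )

    @classmethod
    def mk2(cls, **kw) -> "SubstitutionModel":
        """Binary symmetric two-state model (Cavender–Farris–Neyman)."""
        return cls(alphabet="binary", family="FSM", name="Mk2", **kw)

    @classmethod
    def nonreversible(cls, rate_matrix, **kw) -> "SubstitutionModel":
        """Fully general 12-parameter DNA model; pi is its stationary vector."""
        rates = np.asarray(rate_matrix, dtype=float)
        q = rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        ns = null_space(q.T)
        pi = np.abs(ns[:, 0])
        pi = pi / pi.sum()
        return cls(
            alphabet="DNA",
            family="FSM",
            base_freqs=pi,
            relative_rates=rates,
            reversible=False,
            name="nonreversible",
            **kw,
        )


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Instantaneous rate matrix Q, normalized to mean substitution rate 1.

    Reversible: ``q_ij = r_ij * pi_j`` (GTR form; JC/HKY/Mk2 are special
    cases).  Nonreversible: the relative-rate matrix is used directly.  The
    normalization divides Q by ``-sum_i pi_i q_ii`` so branch lengths are in
    expected substitutions per site.
    """
    pi = model.base_freqs
    r = model.relative_rates
    if model.reversible:
        q = r * pi[np.newaxis, :]
    else:
        q = r.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / mu


def fsm_transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Transition probability matrix ``exp(Q t)`` for a finite-site model."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    q = build_rate_matrix(model)
    p = expm(q * t)
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Ancestral genome
# ---------------------------------------------------------------------------


@dataclass
class AncestralGenome:
    """The genome at the root: two haplotypes plus per-site rate multipliers."""

    maternal: np.ndarray
    paternal: np.ndarray
    site_rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        if self.maternal.shape != self.paternal.shape:
            raise ValueError("haplotypes must have equal length")
        if self.site_rates is None:
            self.site_rates = np.ones(self.length)
        self.site_rates = np.asarray(self.site_rates, dtype=float)
        if np.any(self.site_rates <= 0):
            raise ValueError("site rate multipliers must be positive")

    @property
    def length(self) -> int:
        return int(self.maternal.shape[0])


def generate_ancestral_genome(
    l: int,
    base_freqs,
    rng: np.random.Generator,
    gamma_site_alpha: Optional[float] = None,
    alphabet: str = "DNA",
) -> AncestralGenome:
    """Simulate the ancestral genome: iid sites from ``base_freqs``.

    Both haplotypes are identical at generation (a homozygous ancestor);
    heterozygosity enters only through :func:`add_germline_variants`.
    Optional gamma among-site rate multipliers (mean 1, shape alpha) are
    drawn here and used by the FSM simulator.
    """
    if l < 1:
        raise ValueError(f"genome length must be >= 1, got {l}")
    pi = np.asarray(base_freqs, dtype=float)
    k = 4 if alphabet == "DNA" else 2
    if pi.shape != (k,) or np.any(pi < 0) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("base_freqs must be a probability simplex over the alphabet")
    seq = rng.choice(k, size=l, p=pi).astype(np.int8)
    rates = (
        rng.gamma(gamma_site_alpha, 1.0 / gamma_site_alpha, size=l)
        if gamma_site_alpha
        else np.ones(l)
    )
    return AncestralGenome(
        maternal=seq, paternal=seq.copy(), site_rates=rates, alphabet=alphabet
    )


def load_ancestral_genome_fasta(
    path, gamma_site_alpha: Optional[float] = None, rng: Optional[np.random.Generator] = None
) -> AncestralGenome:
    """Load a user-supplied ancestral genome from FASTA (first record).

    The sequence is used verbatim as both haplotypes.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    mapping = {b: i for i, b in enumerate(DNA)}
    try:
        seq = np.array([mapping[c] for c in str(record.seq).upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in ancestral FASTA: {exc}") from exc
    rates = None
    if gamma_site_alpha:
        if rng is None:
            raise ValueError("rng required to draw site rate multipliers")
        rates = rng.gamma(gamma_site_alpha, 1.0 / gamma_site_alpha, size=seq.shape[0])
    return AncestralGenome(maternal=seq, paternal=seq.copy(), site_rates=rates)


def add_germline_variants(
    genome: AncestralGenome,
    rate: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> AncestralGenome:
    """Make each site heterozygous with probability ``rate``.

    The haplotype to alter is chosen uniformly and the target allele follows
    the model's relative rates away from the current allele.  Returns a new
    genome; the input is untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"germline rate must be in [0,1], got {rate}")
    mat = genome.maternal.copy()
    pat = genome.paternal.copy()
    hit = np.flatnonzero(rng.random(genome.length) < rate)
    if hit.size:
        k = model.n_states
        rows = model.relative_rates / model.relative_rates.sum(axis=1, keepdims=True)
        haps = rng.integers(0, 2, size=hit.size)
        for site, hap in zip(hit, haps):
            target = mat if hap == 0 else pat
            cur = int(target[site])
            target[site] = rng.choice(k, p=rows[cur])
    return AncestralGenome(
        maternal=mat,
        paternal=pat,
        site_rates=genome.site_rates.copy(),
        alphabet=genome.alphabet,
    )


# ---------------------------------------------------------------------------
# Placing events on branches
# ---------------------------------------------------------------------------


def _mutable_branches(
    tree: CellGenealogy, include_outgroup_branch: bool = False
) -> list[TreeNode]:
    """Branches that can carry somatic events (identified by child node).

    The outgroup branch is excluded by default so that every somatic event is
    visible in at least one sampled cell.
    """
    out = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        if node.label == LABEL_OUTGROUP and not include_outgroup_branch:
            continue
        out.append(node)
    return out


def place_mutations_on_branches(
    tree: CellGenealogy,
    rng: np.random.Generator,
    n_mutations: Optional[int] = None,
    rate: Optional[float] = None,
    include_outgroup_branch: bool = False,
) -> list[tuple[TreeNode, int]]:
    """Allocate mutation counts to branches.

    Fixed-count mode places exactly ``n_mutations`` by a multinomial with
    probabilities proportional to branch length; rate mode draws
    ``Poisson(rate * branch_length)`` independently per branch (``rate`` is a
    genome-wide rate per unit of branch length, coalescent units).
    """
    if (n_mutations is None) == (rate is None):
        raise ValueError("specify exactly one of n_mutations or rate")
    branches = _mutable_branches(tree, include_outgroup_branch)
    lengths = np.array([b.branch_length for b in branches], dtype=float)
    total = lengths.sum()
    if n_mutations is not None:
        if n_mutations < 0:
            raise ValueError("n_mutations must be nonnegative")
        if n_mutations == 0:
            return []
        if total <= 0:
            raise ValueError("tree has zero total branch length")
        counts = rng.multinomial(n_mutations, lengths / total)
    else:
        counts = rng.poisson(rate * lengths)
    return [(b, int(c)) for b, c in zip(branches, counts) if c > 0]


def expected_segregating_sites(n_cells: int, rate: float) -> float:
    """Watterson expectation for rate-mode ISM on a constant-size coalescent.

    ``E[S] = rate * E[total tree length] = rate * 2 * sum_{i=1}^{n-1} 1/i``
    with rate the genome-wide mutation rate per coalescent time unit.
    """
    return rate * 2.0 * sum(1.0 / i for i in range(1, n_cells))


# ---------------------------------------------------------------------------
# Event sampling (ISM / signatures / haploid ISM)
# ---------------------------------------------------------------------------


def _sample_ism_snv_events(
    tree: CellGenealogy,
    genome: AncestralGenome,
    placements: Sequence[tuple[TreeNode, int]],
    rng: np.random.Generator,
    model: Optional[SubstitutionModel] = None,
) -> list[MutationEvent]:
    l = genome.length
    total = sum(c for _, c in placements)
    if genome.alphabet == "binary":
        # binary ISM flips 0 -> 1 only, so a mutable site must carry a 0
        eligible = np.flatnonzero((genome.maternal == 0) | (genome.paternal == 0))
    else:
        eligible = np.arange(l)
    if total > eligible.size:
        raise ISMExhaustedError(
            f"{total} ISM mutations requested but only {eligible.size} "
            "mutable sites available"
        )
    if total == 0:
        return []
    sites = rng.choice(eligible, size=total, replace=False)
    haps = rng.integers(0, 2, size=total)
    k = 4 if genome.alphabet == "DNA" else 2
    if model is not None and genome.alphabet == "DNA":
        rows = model.relative_rates / model.relative_rates.sum(axis=1, keepdims=True)
    else:
        rows = None
    events = []
    idx = 0
    for node, count in placements:
        for _ in range(count):
            site = int(sites[idx])
            hap = int(haps[idx])
            idx += 1
            if genome.alphabet == "binary":
                # pick a haplotype that still carries the ancestral 0
                zeros = [
                    h
                    for h, arr in ((0, genome.maternal), (1, genome.paternal))
                    if arr[site] == 0
                ]
                if hap not in zeros:  # germline 1 on the drawn haplotype
                    hap = zeros[0]
                src = genome.maternal if hap == 0 else genome.paternal
                cur = int(src[site])
                to = 1
            else:
                src = genome.maternal if hap == 0 else genome.paternal
                cur = int(src[site])
                if rows is not None:
                    to = int(rng.choice(k, p=rows[cur]))
                else:
                    to = int(rng.choice([a for a in range(k) if a != cur]))
            events.append(
                MutationEvent(
                    node_id=node.id,
                    site=site,
                    haplotype=hap,
                    kind="SNV",
                    from_allele=cur,
                    to_allele=to,
                    germline_site=bool(genome.maternal[site] != genome.paternal[site]),
                )
            )
    return events


def signature_channels() -> list[str]:
    """The 96 substitution channels in standard order, e.g. ``A[C>A]A``.

    Substitution types iterate C>A, C>G, C>T, T>A, T>C, T>G (pyrimidine
    convention), with 5' then 3' flanks each over A, C, G, T.
    """
    subs = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
    return [
        f"{l5}[{ref}>{alt}]{r3}"
        for ref, alt in subs
        for l5 in DNA
        for r3 in DNA
    ]


def load_signature_catalogue(path=None) -> pd.DataFrame:
    """Load the bundled mutational-signature catalogue (30 x 96 frequencies).

    The bundled table is a *synthetic* stand-in catalogue with the structure
    of published single-base-substitution signatures (30 signatures, 96
    trinucleotide channels summing to 1 per signature); pass ``path`` to use
    a real catalogue in the same TSV layout (rows = signatures, columns =
    channels named like ``A[C>A]A``).
    """
    if path is None:
        path = Path(__file__).parent / "data" / "signatures_synthetic_96.tsv"
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = signature_channels()
    if list(df.columns) != expected:
        df = df[expected]  # raises KeyError if channels are missing
    return df


def _site_context_keys(genome: AncestralGenome) -> dict[int, tuple[int, int, int]]:
    """Map interior sites to (pyr_ref, 5', 3') context keys.

    Contexts are read off the maternal ancestral haplotype; purine sites are
    reverse-complemented so the mutated base is always reported as the
    pyrimidine of the Watson–Crick pair.  Terminal sites (no neighbor) are
    excluded.
    """
    seq = genome.maternal
    keys = {}
    for i in range(1, genome.length - 1):
        b = int(seq[i])
        if b in _PYRIMIDINES:
            keys[i] = (b, int(seq[i - 1]), int(seq[i + 1]))
        else:
            keys[i] = (
                int(_COMPLEMENT[b]),
                int(_COMPLEMENT[int(seq[i + 1])]),
                int(_COMPLEMENT[int(seq[i - 1])]),
            )
    return keys


def _channel_table() -> list[tuple[int, int, int, int]]:
    """Per channel: (pyr_ref, alt, 5', 3') as allele codes."""
    table = []
    subs = [(1, 0), (1, 2), (1, 3), (3, 0), (3, 1), (3, 2)]  # C>A.. T>G
    for ref, alt in subs:
        for l5 in range(4):
            for r3 in range(4):
                table.append((ref, alt, l5, r3))
    return table


def _sample_signature_events(
    tree: CellGenealogy,
    genome: AncestralGenome,
    signature: np.ndarray,
    placements: Sequence[tuple[TreeNode, int]],
    rng: np.random.Generator,
) -> list[MutationEvent]:
    if genome.alphabet != "DNA":
        raise ValueError("signature model requires the DNA alphabet")
    signature = np.asarray(signature, dtype=float)
    total = sum(c for _, c in placements)
    if total == 0:
        return []
    site_keys = _site_context_keys(genome)
    if total > len(site_keys):
        raise ISMExhaustedError(
            f"{total} signature mutations requested but only {len(site_keys)} "
            "interior sites available"
        )
    pools: dict[tuple[int, int, int], list[int]] = {}
    for site, key in site_keys.items():
        pools.setdefault(key, []).append(site)
    channels = _channel_table()
    chan_key = [(ref, l5, r3) for ref, _alt, l5, r3 in channels]

    events = []
    for node, count in placements:
        for _ in range(count):
            mass = np.array(
                [
                    signature[c] if pools.get(chan_key[c]) else 0.0
                    for c in range(96)
                ]
            )
            tot = mass.sum()
            if tot <= 0:
                raise ValueError(
                    "no unmutated site remains in any context with positive "
                    "signature mass"
                )
            chan = int(rng.choice(96, p=mass / tot))
            pool = pools[chan_key[chan]]
            site = pool.pop(int(rng.integers(len(pool))))
            hap = int(rng.integers(0, 2))
            src = genome.maternal if hap == 0 else genome.paternal
            base = int(genome.maternal[site])
            alt = channels[chan][1]
            to = alt if base in _PYRIMIDINES else int(_COMPLEMENT[alt])
            events.append(
                MutationEvent(
                    node_id=node.id,
                    site=site,
                    haplotype=hap,
                    kind="SNV",
                    from_allele=int(src[site]),
                    to_allele=to,
                    channel=chan,
                )
            )
    return events


def _sample_haploid_ism_events(
    tree: CellGenealogy,
    genome: AncestralGenome,
    kind: str,
    rng: np.random.Generator,
    n_events: Optional[int] = None,
    rate: Optional[float] = None,
    used: Optional[set] = None,
) -> list[MutationEvent]:
    """Sample cnLOH or deletion events under a haploid ISM.

    Each event occupies a unique (site, haplotype) slot for its kind, so at
    most ``2 * l`` events fit; a repeat at the same site must land on the
    other parental genome.
    """
    placements = place_mutations_on_branches(
        tree, rng, n_mutations=n_events, rate=rate
    )
    total = sum(c for _, c in placements)
    if total == 0:
        return []
    l = genome.length
    used = set() if used is None else used
    if total > 2 * l - len(used):
        raise ISMExhaustedError(
            f"{total} {kind} events requested but only {2 * l - len(used)} "
            "(site, haplotype) slots remain"
        )
    free = [(s, h) for s in range(l) for h in (0, 1) if (s, h) not in used]
    picks = rng.choice(len(free), size=total, replace=False)
    events = []
    idx = 0
    for node, count in placements:
        for _ in range(count):
            site, hap = free[int(picks[idx])]
            idx += 1
            used.add((site, hap))
            events.append(
                MutationEvent(node_id=node.id, site=site, haplotype=hap, kind=kind)
            )
    return events


# ---------------------------------------------------------------------------
# The evolution engine
# ---------------------------------------------------------------------------


class _FSMSampler:
    """Samples child states along branches under a finite-site model.

    Uses one eigendecomposition of Q and vectorizes ``exp(Q * t_s)`` over the
    per-site branch lengths (branch length x site rate multiplier), which is
    exact and much faster than per-site matrix exponentials.
    """

    def __init__(self, model: SubstitutionModel):
        self.k = model.n_states
        q = build_rate_matrix(model)
        self.evals, self.evecs = np.linalg.eig(q)
        self.inv = np.linalg.inv(self.evecs)

    def transition_rows(self, ts: np.ndarray, parent: np.ndarray) -> np.ndarray:
        """Rows P_t[parent_s, :] for each site s with its own time t_s."""
        e = np.exp(np.multiply.outer(ts, self.evals))  # (l, k)
        rows = np.einsum(
            "ik,sk,kj->sij", self.evecs, e, self.inv
        ).real  # (l, k, k)
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=2, keepdims=True)
        return rows[np.arange(parent.shape[0]), parent]

    def evolve(
        self, parent: np.ndarray, ts: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        probs = self.transition_rows(ts, parent)
        u = rng.random(parent.shape[0])
        cum = np.cumsum(probs, axis=1)
        return (u[:, None] > cum).sum(axis=1).astype(np.int8)


@dataclass
class GenotypeResult:
    """True genotypes per sampled cell x site plus the event log."""

    maternal: np.ndarray  # (n_cells, l) int8, DEL = -1
    paternal: np.ndarray
    events: list[MutationEvent]
    outgroup_maternal: Optional[np.ndarray] = None
    outgroup_paternal: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.maternal.shape[0]

    @property
    def n_sites(self) -> int:
        return self.maternal.shape[1]


def _evolve(
    tree: CellGenealogy,
    genome: AncestralGenome,
    events: Sequence[MutationEvent],
    rng: np.random.Generator,
    fsm: Optional[_FSMSampler] = None,
) -> GenotypeResult:
    """Pre-order traversal applying FSM substitutions and discrete events.

    Per branch, events apply in the order SNV, then cnLOH, then deletion: a
    deletion silences the site on that haplotype regardless of what the
    earlier events wrote.
    """
    order = {"SNV": 0, "cnLOH": 1, "deletion": 2}
    by_node: dict[int, list[MutationEvent]] = {}
    for ev in events:
        by_node.setdefault(ev.node_id, []).append(ev)
    for evs in by_node.values():
        evs.sort(key=lambda e: order[e.kind])

    tip_seqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    og: Optional[tuple[np.ndarray, np.ndarray]] = None

    stack: list[tuple[TreeNode, np.ndarray, np.ndarray]] = [
        (tree.root, genome.maternal.copy(), genome.paternal.copy())
    ]
    while stack:
        node, mat, pat = stack.pop()
        if node.parent is not None:
            if fsm is not None:
                ts = node.branch_length * genome.site_rates
                mat = fsm.evolve(mat, ts, rng)
                pat = fsm.evolve(pat, ts, rng)
            else:
                mat = mat.copy()
                pat = pat.copy()
            for ev in by_node.get(node.id, ()):
                target = mat if ev.haplotype == 0 else pat
                other = pat if ev.haplotype == 0 else mat
                if ev.kind == "SNV":
                    if target[ev.site] == DEL:
                        continue  # allele already deleted upstream
                    target[ev.site] = ev.to_allele
                elif ev.kind == "cnLOH":
                    ev.from_allele = int(target[ev.site])
                    ev.to_allele = int(other[ev.site])
                    target[ev.site] = other[ev.site]
                else:  # deletion
                    ev.from_allele = int(target[ev.site])
                    ev.to_allele = DEL
                    target[ev.site] = DEL
        if node.is_leaf:
            if node.label == LABEL_OUTGROUP:
                og = (mat, pat)
            else:
                tip_seqs[node.name or f"node{node.id}"] = (mat, pat)
        else:
            # children share the parent's arrays; each branch copies on entry
            for child in reversed(node.children):
                stack.append((child, mat, pat))

    tips = tree.cell_tips()
    mat = np.stack([tip_seqs[t.name][0] for t in tips])
    pat = np.stack([tip_seqs[t.name][1] for t in tips])
    return GenotypeResult(
        maternal=mat,
        paternal=pat,
        events=list(events),
        outgroup_maternal=og[0] if og else None,
        outgroup_paternal=og[1] if og else None,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def evolve_ism_diploid(
    tree: CellGenealogy,
    genome: AncestralGenome,
    placements: Sequence[tuple[TreeNode, int]],
    rng: np.random.Generator,
    model: Optional[SubstitutionModel] = None,
) -> GenotypeResult:
    """Evolve genotypes under the diploid infinite-site model.

    Each mutation hits a uniformly chosen previously unmutated site on the
    maternal or paternal haplotype with probability 1/2; descendants inherit
    the derived allele, so the number of segregating sites among the sampled
    cells equals the number of placed mutations.
    """
    events = _sample_ism_snv_events(tree, genome, placements, rng, model)
    return _evolve(tree, genome, events, rng)


def evolve_signature_mutations(
    tree: CellGenealogy,
    genome: AncestralGenome,
    signature: np.ndarray,
    placements: Sequence[tuple[TreeNode, int]],
    rng: np.random.Generator,
) -> GenotypeResult:
    """ISM evolution with trinucleotide-signature channel sampling.

    Each mutation's (context, change) channel is drawn from the signature
    restricted and renormalized to contexts still available among unmutated
    interior sites, in pyrimidine-strand convention.
    """
    events = _sample_signature_events(tree, genome, signature, placements, rng)
    return _evolve(tree, genome, events, rng)


def evolve_fsm_along_tree(
    tree: CellGenealogy,
    genome: AncestralGenome,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> GenotypeResult:
    """Evolve each haplotype/site independently under a finite-site model."""
    return _evolve(tree, genome, [], rng, fsm=_FSMSampler(model))


def apply_cnloh(
    tree: CellGenealogy,
    genome: AncestralGenome,
    rng: np.random.Generator,
    n_events: Optional[int] = None,
    rate: Optional[float] = None,
    prior_events: Sequence[MutationEvent] = (),
    fsm_model: Optional[SubstitutionModel] = None,
) -> GenotypeResult:
    """Add copy-neutral LOH events and re-evolve the genotype matrices.

    A cnLOH copies one parental allele over the other at the event time; the
    new state is inherited by descendants.  Haploid ISM: the same (site,
    haplotype) pair is never hit twice.
    """
    used = {
        (e.site, e.haplotype) for e in prior_events if e.kind == "cnLOH"
    }
    new = _sample_haploid_ism_events(
        tree, genome, "cnLOH", rng, n_events=n_events, rate=rate, used=used
    )
    fsm = _FSMSampler(fsm_model) if fsm_model is not None else None
    return _evolve(tree, genome, list(prior_events) + new, rng, fsm=fsm)


def apply_deletions(
    tree: CellGenealogy,
    genome: AncestralGenome,
    rng: np.random.Generator,
    n_events: Optional[int] = None,
    rate: Optional[float] = None,
    prior_events: Sequence[MutationEvent] = (),
    fsm_model: Optional[SubstitutionModel] = None,
) -> GenotypeResult:
    """Add point deletions (haploid ISM) and re-evolve the genotype matrices.

    The target allele becomes the deleted marker for all descendants; deleted
    alleles contribute no sequencing reads downstream.
    """
    used = {
        (e.site, e.haplotype) for e in prior_events if e.kind == "deletion"
    }
    new = _sample_haploid_ism_events(
        tree, genome, "deletion", rng, n_events=n_events, rate=rate, used=used
    )
    fsm = _FSMSampler(fsm_model) if fsm_model is not None else None
    return _evolve(tree, genome, list(prior_events) + new, rng, fsm=fsm)


def evolve_genotypes(
    tree: CellGenealogy,
    genome: AncestralGenome,
    model: SubstitutionModel,
    rng: np.random.Generator,
    n_cnloh: int = 0,
    cnloh_rate: Optional[float] = None,
    n_deletions: int = 0,
    deletion_rate: Optional[float] = None,
) -> GenotypeResult:
    """Full somatic-evolution pipeline: SNVs, then cnLOH, then deletions.

    SNV placement follows the model's ``fixed_mutations`` or
    ``mutation_rate`` (genome-wide, per unit branch length).  cnLOH and
    deletion events are placed on branches proportionally to length with
    their own counts or rates, independent of the SNVs.
    """
    events: list[MutationEvent] = []
    fsm = None
    if model.family == "FSM":
        fsm = _FSMSampler(model)
    else:
        placements = place_mutations_on_branches(
            tree,
            rng,
            n_mutations=model.fixed_mutations,
            rate=model.mutation_rate if model.fixed_mutations is None else None,
        )
        if model.family == "trinuc_signature":
            events += _sample_signature_events(
                tree, genome, model.signature, placements, rng
            )
        else:
            events += _sample_ism_snv_events(tree, genome, placements, rng, model)
    if n_cnloh or cnloh_rate:
        events += _sample_haploid_ism_events(
            tree, genome, "cnLOH", rng,
            n_events=n_cnloh or None, rate=cnloh_rate,
        )
    if n_deletions or deletion_rate:
        events += _sample_haploid_ism_events(
            tree, genome, "deletion", rng,
            n_events=n_deletions or None, rate=deletion_rate,
        )
    return _evolve(tree, genome, events, rng, fsm=fsm)
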
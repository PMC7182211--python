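"""Coalescent genealogies for samples of single cells.

This module simulates the timed genealogy of a sample of cells drawn from a
large somatic cell population under the neutral Kingman coalescent, with
constant size, continuous exponential growth, piecewise ("multi-period")
demographies, or a cancer parameterization in which exponential growth arises
as the difference between cell birth and death rates.

Time runs backward from the sampled cells (age 0) and is measured in units of
``N0`` generations (standard coalescent scaling), so that with ``k`` ancestral
lineages the waiting time to the next coalescence under constant size is
exponential with rate ``k(k-1)/2``.  Variable population size is handled by
the usual cumulative-intensity time transformation: a waiting time drawn on
the constant-size scale is mapped to real time by inverting
``Lambda(t) = int_0^t N0/N(s) ds``.

After the sample genealogy is built, two optional branches can be attached: a
*root branch* joining the sample MRCA (sMRCA) to its common ancestor with an
outgroup cell (oMRCA), and an *outgroup branch* from the oMRCA down to the
outgroup tip (e.g. a healthy cell used as reference for a tumor sample).
Among-lineage rate variation multiplies branch lengths by independent
mean-one gamma draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "TreeNode",
    "CellGenealogy",
    "Demography",
    "GenealogyConfig",
    "NewickParseError",
    "simulate_coalescent_genealogy",
    "simulate_cancer_genealogy",
    "transform_time_growth",
    "attach_root_and_outgroup",
    "apply_lineage_rate_variation",
    "parse_newick",
    "write_newick",
]

LABEL_TIP = "cell"
LABEL_INTERNAL = "internal"
LABEL_SMRCA = "sMRCA"
LABEL_OMRCA = "oMRCA"
LABEL_OUTGROUP = "outgroup"


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


@dataclass
class TreeNode:
    """A node of a cell genealogy.

    ``time`` is the node's age (coalescent units; sampled cells sit at 0) and
    the branch to the parent has length ``(parent.time - time) *
    rate_multiplier``.
    """

    id: int
    time: float = 0.0
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)
    rate_multiplier: float = 1.0
    label: str = LABEL_INTERNAL
    name: Optional[str] = None

    @property
    def branch_length(self) -> float:
        if self.parent is None:
            return 0.0
        return (self.parent.time - self.time) * self.rate_multiplier

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode(id={self.id}, time={self.time:.4g}, label={self.label!r})"


class CellGenealogy:
    """A rooted, timed binary genealogy over sampled cells.

    The root is the oMRCA when a root/outgroup branch has been attached, and
    the sMRCA otherwise.  Cell tips are named ``cell1 .. celln`` and the
    outgroup tip (if present) ``outgroup``.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = list(self.preorder())
        return iter(reversed(out))

    @property
    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    @property
    def smrca(self) -> TreeNode:
        for node in self.preorder():
            if node.label == LABEL_SMRCA:
                return node
        raise ValueError("genealogy has no sMRCA node")

    @property
    def omrca(self) -> Optional[TreeNode]:
        for node in self.preorder():
            if node.label == LABEL_OMRCA:
                return node
        return None

    @property
    def outgroup(self) -> Optional[TreeNode]:
        for node in self.preorder():
            if node.label == LABEL_OUTGROUP:
                return node
        return None

    def cell_tips(self) -> list[TreeNode]:
        """Sampled-cell tips ordered by cell index (``cell1`` first)."""
        tips = [n for n in self.preorder() if n.is_leaf and n.label == LABEL_TIP]

        def key(node: TreeNode):
            name = node.name or ""
            digits = "".join(ch for ch in name if ch.isdigit())
            return (int(digits) if digits else 0, name)

        return sorted(tips, key=key)

    @property
    def n_cells(self) -> int:
        return len(self.cell_tips())

    @property
    def tmrca(self) -> float:
        """Age of the sample MRCA (coalescent units)."""
        return self.smrca.time

    def total_branch_length(self, include_outgroup: bool = True) -> float:
        total = 0.0
        for node in self.preorder():
            if node.parent is None:
                continue
            if not include_outgroup and node.label == LABEL_OUTGROUP:
                continue
            total += node.branch_length
        return total

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        n_smrca = 0
        for node in self.preorder():
            if len(node.children) > 2:
                raise ValueError(f"node {node.id} has {len(node.children)} children")
            if node.label == LABEL_SMRCA:
                n_smrca += 1
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("broken parent link")
                if child.label != LABEL_OUTGROUP and node.time < child.time - 1e-12:
                    raise ValueError(
                        f"parent {node.id} not older than child {child.id}"
                    )
                if child.branch_length < -1e-12:
                    raise ValueError(f"negative branch length at node {child.id}")
        if n_smrca != 1:
            raise ValueError(f"expected exactly one sMRCA, found {n_smrca}")


# ---------------------------------------------------------------------------
# Demography and time transformation
# ---------------------------------------------------------------------------


@dataclass
class Demography:
    """Backward-time demographic model of the cell population.

    ``N0`` is the present-day effective size; ``growth_rate`` is the
    per-generation exponential growth rate ``g`` (so the coalescent-scale
    growth is ``G = g * N0`` and the backward size is
    ``N(t) = N0 * exp(-G t)`` with ``t`` in units of ``N0`` generations).

    ``periods`` (multi-period model) is an ordered list of
    ``(start, end, size, growth)`` tuples going backward in time, times in
    coalescent units, ``size`` an absolute effective size at the period start
    and ``growth`` a per-generation rate within the period.  The last period
    may end at ``inf``.

    The cancer model has overlapping generations and grows at the difference
    between the cell birth and death rates; it is mapped onto the exponential
    coalescent with ``g = birth_rate - death_rate``.
    """

    model: str = "constant"
    N0: int = 10_000
    growth_rate: float = 0.0
    periods: Optional[Sequence[tuple]] = None
    birth_rate: Optional[float] = None
    death_rate: Optional[float] = None

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant(cls, N0: int) -> "Demography":
        return cls(model="constant", N0=N0)

    @classmethod
    def exponential(cls, N0: int, growth_rate: float) -> "Demography":
        return cls(model="exponential", N0=N0, growth_rate=growth_rate)

    @classmethod
    def multi_period(cls, N0: int, periods: Sequence[tuple]) -> "Demography":
        return cls(model="multi_period", N0=N0, periods=list(periods))

    @classmethod
    def cancer(cls, N0: int, birth_rate: float, death_rate: float) -> "Demography":
        if birth_rate <= death_rate:
            raise ValueError(
                "cancer model requires birth_rate > death_rate "
                f"(got birth={birth_rate}, death={death_rate})"
            )
        if death_rate < 0:
            raise ValueError("death_rate must be nonnegative")
        return cls(
            model="cancer", N0=N0, birth_rate=birth_rate, death_rate=death_rate
        )

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError(f"N0 must be positive, got {self.N0}")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be nonnegative")
        if self.model == "multi_period":
            if not self.periods:
                raise ValueError("multi_period model requires periods")
            prev_end = 0.0
            for start, end, size, growth in self.periods:
                if not math.isclose(start, prev_end, abs_tol=1e-12):
                    raise ValueError("periods must be contiguous from time 0")
                if end <= start:
                    raise ValueError("period end must exceed start")
                if size <= 0:
                    raise ValueError("period size must be positive")
                prev_end = end

    # -- intensity algebra -------------------------------------------------

    def _scaled_growth(self) -> float:
        """Growth on the coalescent time scale (per N0 generations)."""
        if self.model == "cancer":
            return (self.birth_rate - self.death_rate) * self.N0
        return self.growth_rate * self.N0

    def _segments(self) -> list[tuple[float, float, float, float]]:
        """Piecewise regimes as (start, end, nu_at_start, G) going backward.

        ``nu`` is relative size N/N0 and ``G`` is growth per coalescent time
        unit.  A final constant segment extends the demography to infinity at
        the size reached at the end of the last declared period.
        """
        if self.model == "constant":
            return [(0.0, math.inf, 1.0, 0.0)]
        if self.model in ("exponential", "cancer"):
            return [(0.0, math.inf, 1.0, self._scaled_growth())]
        segs = []
        for start, end, size, growth in self.periods:
            segs.append((start, end, size / self.N0, growth * self.N0))
        start, end, nu, G = segs[-1]
        if math.isfinite(end):
            nu_end = nu * math.exp(-G * (end - start))
            segs.append((end, math.inf, nu_end, 0.0))
        return segs

    @staticmethod
    def _segment_intensity(nu: float, G: float, dt: float) -> float:
        """Intensity accumulated over ``dt`` within one regime."""
        if G == 0.0:
            return dt / nu
        return math.expm1(G * dt) / (nu * G)

    def coalescent_intensity(self, t: float) -> float:
        """Cumulative coalescent intensity Lambda(t) = int_0^t N0/N(s) ds."""
        if t < 0:
            raise ValueError("time must be nonnegative")
        total = 0.0
        for start, end, nu, G in self._segments():
            if t <= start:
                break
            total += self._segment_intensity(nu, G, min(t, end) - start)
        return total

    def inverse_intensity(self, u: float) -> float:
        """Real time whose cumulative intensity equals ``u``."""
        if u < 0:
            raise ValueError("intensity must be nonnegative")
        acc = 0.0
        segs = self._segments()
        for i, (start, end, nu, G) in enumerate(segs):
            span = end - start
            cap = (
                math.inf
                if math.isinf(span)
                else self._segment_intensity(nu, G, span)
            )
            remain = u - acc
            if remain <= cap or i == len(segs) - 1:
                if G == 0.0:
                    return start + remain * nu
                return start + math.log1p(G * nu * remain) / G
            acc += cap
        raise AssertionError("unreachable")


def transform_time_growth(t_constant: float, demography: Demography) -> float:
    """Map a constant-size coalescent time to real time under variable size.

    Returns the real time whose cumulative coalescent intensity equals
    ``t_constant``; strictly increasing in its argument, and the identity
    when the growth rate is zero.
    """
    if t_constant < 0:
        raise ValueError("time must be nonnegative")
    if demography.model not in ("exponential", "multi_period", "cancer", "constant"):
        raise ValueError(f"unsupported demography model {demography.model!r}")
    return demography.inverse_intensity(t_constant)


@dataclass
class GenealogyConfig:
    """Bundled genealogy options (mirrors the CLI flags)."""

    n_cells: int = 10
    root_ratio: float = 0.0
    outgroup_ratio: float = 0.0
    lineage_rate_alpha: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.root_ratio < 0 or self.outgroup_ratio < 0:
            raise ValueError("root/outgroup ratios must be nonnegative")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_coalescent_genealogy(
    n_cells: int, demography: Demography, rng: np.random.Generator
) -> CellGenealogy:
    """Simulate a neutral coalescent genealogy for ``n_cells`` sampled cells.

    Builds a binary ultrametric tree with tips at time 0 and ``n_cells - 1``
    coalescences.  With ``k`` lineages the waiting time on the constant-size
    scale is exponential with rate ``k(k-1)/2``; variable size enters through
    the cumulative-intensity time transformation.
    """
    if n_cells < 2:
        raise ValueError(f"n_cells must be >= 2, got {n_cells}")

    next_id = 0
    active: list[TreeNode] = []
    for i in range(n_cells):
        active.append(
            TreeNode(id=next_id, time=0.0, label=LABEL_TIP, name=f"cell{i + 1}")
        )
        next_id += 1

    u = 0.0  # cumulative intensity (constant-size scale)
    k = n_cells
    while k > 1:
        rate = k * (k - 1) / 2.0
        u += rng.exponential(1.0 / rate)
        t = demography.inverse_intensity(u)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = active.pop(j)
        left = active.pop(i)
        parent = TreeNode(id=next_id, time=t, label=LABEL_INTERNAL)
        next_id += 1
        parent.children = [left, right]
        left.parent = parent
        right.parent = parent
        active.append(parent)
        k -= 1

    root = active[0]
    root.label = LABEL_SMRCA
    tree = CellGenealogy(root)
    return tree


def simulate_cancer_genealogy(
    n_cells: int,
    birth_rate: float,
    death_rate: float,
    N0: int,
    rng: np.random.Generator,
) -> CellGenealogy:
    """Genealogy of cells sampled from an exponentially expanding tumor.

    The cancer coalescent has overlapping generations and an effective growth
    rate equal to the difference between the cell birth and death rates; only
    that difference affects the genealogy distribution here.
    """
    demography = Demography.cancer(N0=N0, birth_rate=birth_rate, death_rate=death_rate)
    return simulate_coalescent_genealogy(n_cells, demography, rng)


def attach_root_and_outgroup(
    tree: CellGenealogy, root_ratio: float, outgroup_ratio: float
) -> CellGenealogy:
    """Attach the root branch (sMRCA→oMRCA) and the outgroup branch/tip.

    Both branch lengths are expressed as a ratio of the sMRCA depth (the
    sample tree height).  A ratio of 0 suppresses the corresponding element:
    with both ratios 0 the tree is returned unchanged.  The outgroup tip is
    placed at time ``oMRCA.time - outgroup_ratio * depth`` so that branch
    lengths remain consistent with node ages; the outgroup tip's age may
    therefore differ from 0 (the tree is no longer ultrametric).
    """
    if root_ratio < 0 or outgroup_ratio < 0:
        raise ValueError("root_ratio and outgroup_ratio must be nonnegative")
    smrca = tree.smrca
    if root_ratio == 0 and outgroup_ratio == 0:
        return tree
    depth = smrca.time
    max_id = max(n.id for n in tree.preorder())
    omrca = TreeNode(
        id=max_id + 1, time=depth + root_ratio * depth, label=LABEL_OMRCA
    )
    omrca.children = [smrca]
    smrca.parent = omrca
    if outgroup_ratio > 0:
        og = TreeNode(
            id=max_id + 2,
            time=omrca.time - outgroup_ratio * depth,
            label=LABEL_OUTGROUP,
            name="outgroup",
        )
        og.parent = omrca
        omrca.children.append(og)
    tree.root = omrca
    return tree


def apply_lineage_rate_variation(
    tree: CellGenealogy, alpha: float, rng: np.random.Generator
) -> CellGenealogy:
    """Multiply each branch by an independent mean-one gamma draw.

    The multiplier has shape ``alpha`` and scale ``1/alpha`` (mean 1,
    variance ``1/alpha``), so expected tree length is preserved while large
    ``alpha`` recovers the strict clock.  Root and outgroup branches receive
    multipliers too.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    for node in tree.preorder():
        if node.parent is None:
            continue
        node.rate_multiplier = float(rng.gamma(alpha, 1.0 / alpha))
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def write_newick(tree: CellGenealogy, precision: int = 10) -> str:
    """Serialize a genealogy to a newick string with branch lengths."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.name or f"node{node.id}"
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.parent is not None:
            body += f":{node.branch_length:.{precision}g}"
        return body

    return fmt(tree.root) + ";"


def parse_newick(text: str) -> CellGenealogy:
    """Parse a newick string (with branch lengths) into a ``CellGenealogy``.

    Node ages are reconstructed from root-to-tip path lengths (age = tree
    height minus depth), so an ultrametric input yields tips at time 0.  The
    root is labelled as the sample MRCA; a tip named ``outgroup``, if present
    as a direct child of the root, turns the root into the oMRCA.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise NewickParseError("newick contains no tree")

    counter = [0]

    def convert(dnode, depth: float) -> tuple[TreeNode, float]:
        node = TreeNode(id=counter[0])
        counter[0] += 1
        node._depth = depth  # type: ignore[attr-defined]
        if dnode.taxon is not None:
            node.name = dnode.taxon.label
        elif dnode.label:
            node.name = dnode.label
        max_depth = depth
        for dchild in dnode.child_nodes():
            bl = dchild.edge.length if dchild.edge.length is not None else 0.0
            child, child_max = convert(dchild, depth + bl)
            child.parent = node
            node.children.append(child)
            max_depth = max(max_depth, child_max)
        if not node.children:
            node.label = LABEL_OUTGROUP if node.name == "outgroup" else LABEL_TIP
        return node, max_depth

    root, height = convert(dtree.seed_node, 0.0)

    def set_times(node: TreeNode) -> None:
        node.time = height - node._depth  # type: ignore[attr-defined]
        del node._depth  # type: ignore[attr-defined]
        for child in node.children:
            set_times(child)

    set_times(root)

    og_children = [c for c in root.children if c.label == LABEL_OUTGROUP]
    if og_children:
        root.label = LABEL_OMRCA
        inner = [c for c in root.children if c.label != LABEL_OUTGROUP]
        if len(inner) == 1:
            inner[0].label = LABEL_SMRCA
        elif inner:  # multifurcating root with outgroup: mark the first
            inner[0].label = LABEL_SMRCA
    else:
        root.label = LABEL_SMRCA
    tree = CellGenealogy(root)
    return tree
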
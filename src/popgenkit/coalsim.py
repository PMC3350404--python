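"""Coalescent simulator: structured populations, migration, recombination,
demographic events, partial selfing, and pluggable mutation models.

The simulator follows the standard backward-in-time scaling of Hudson's
``ms``: time is measured in units of 4N0 generations, so a pair of lineages
in a population of relative size x coalesces at rate 2/x, the per-locus
mutation parameter is theta = 4N0*mu, the recombination parameter is
rho = 4N0*r, and migration rates are 4N0*m.  Under this scaling
E[TMRCA] = 0.5 for a sample of two, the expected total tree length for a
sample of n is the harmonic number a_{n-1}, and E[S] = theta * a_{n-1}.

Recombination is implemented as an ancestral recombination graph with
ancestral-material tracking: each lineage carries intervals of the unit
locus [0, 1); recombination splits a lineage at a uniform breakpoint inside
its ancestral span, coalescence merges overlapping material, and an interval
is retired as soon as a single lineage remains ancestral to it (its local
root).  The output is a partition of [0, 1) into segments, each with its
marginal genealogy.

Partial selfing at rate s raises the inbreeding coefficient F = s/(2-s) and
shrinks the effective size to Ne/(1+F); this is applied as a (1+F) factor on
every coalescence rate.  By default sampled gene copies come from distinct
individuals; with ``diploid=True`` samples are diploid individuals (two
copies each) whose within-individual pairs additionally coalesce instantly
with probability F at sampling time.

Mutators: ``infinite_site`` (each mutation a fresh column, ancestral 'A' /
derived 'T'), ``finite_allele`` (fixed marker positions, weighted transition
matrix, homoplasy possible), ``stepwise`` (microsatellite +/-1 steps) and
``fixed_S`` (exactly S mutations placed on branches proportionally to
length, so only polymorphic sites are generated).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqdata import Alignment, SequenceEntry, Tree, TreeNode

__all__ = [
    "DemographicModel",
    "DemographicEvent",
    "SizeChange",
    "GrowthChange",
    "MigrationChange",
    "PopulationMerge",
    "Bottleneck",
    "SelfingChange",
    "MutatorSpec",
    "GenealogySet",
    "CoalescenceError",
    "UnreachableCoalescenceError",
    "simulate_genealogy",
    "apply_mutator",
    "coalesce",
    "simulate_sfs_batch",
    "MicrosatMatrix",
]


class CoalescenceError(ValueError):
    """Invalid simulator configuration."""


class UnreachableCoalescenceError(RuntimeError):
    """The sample cannot find a common ancestor (isolated populations)."""


# ---------------------------------------------------------------------------
# Parameter objects
# ---------------------------------------------------------------------------

@dataclass
class DemographicEvent:
    """Base class: something that happens at a scaled time >= 0."""

    time: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise CoalescenceError("event time must be >= 0")


@dataclass
class SizeChange(DemographicEvent):
    """Population *pop* takes relative size *size* (growth reset to 0)."""

    pop: int = 0
    size: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.size <= 0:
            raise CoalescenceError("population size must be > 0")


@dataclass
class GrowthChange(DemographicEvent):
    """Exponential growth rate *alpha* for *pop* (all pops when None).

    Backward in time the size is size(t) = size(t_event) * exp(-alpha * dt).
    """

    alpha: float = 0.0
    pop: int | None = None


@dataclass
class MigrationChange(DemographicEvent):
    """Replace the migration matrix (scalar = symmetric island model)."""

    rate: float | None = None
    matrix: Sequence[Sequence[float]] | None = None


@dataclass
class PopulationMerge(DemographicEvent):
    """Backward in time, all lineages of *source* move into *dest*.

    Forward in time this is a population split: *source* was founded from
    *dest* at this date.  Migration to and from *source* stops.
    """

    source: int = 0
    dest: int = 1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.source == self.dest:
            raise CoalescenceError("merge needs two distinct populations")


@dataclass
class Bottleneck(DemographicEvent):
    """Instantaneous bottleneck: *strength* units of extra coalescent time
    applied to *pop* at the event date without advancing branch lengths."""

    pop: int = 0
    strength: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strength < 0:
            raise CoalescenceError("bottleneck strength must be >= 0")


@dataclass
class SelfingChange(DemographicEvent):
    """Selfing rate becomes *s* from this time into the past."""

    s: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0 <= self.s <= 1:
            raise CoalescenceError("selfing rate must be in [0, 1]")


def _selfing_factor(s: float) -> float:
    """1 + F with F = s/(2-s): the coalescence-rate inflation under selfing."""
    return 1.0 + s / (2.0 - s)


@dataclass
class DemographicModel:
    """Demographic side of the simulation (populations, sizes, events).

    Parameters
    ----------
    samples : sequence of int
        Sampled gene copies per population (diploid individuals when
        ``diploid`` is True).
    sizes : sequence of float
        Relative population sizes (1.0 = reference N0).
    migration : float or matrix
        Scaled migration rates 4N0*m; a scalar sets a symmetric island
        model, a matrix gives per-pair rates (diagonal ignored).
    selfing : float
        Selfing rate s in [0, 1].
    recomb_rate : float
        rho = 4N0*r for the whole locus.
    events : list of DemographicEvent
        Applied at their scaled times, oldest last (sorted internally).
    diploid : bool
        Sample diploid individuals (two copies each) with instantaneous
        within-individual coalescence at probability F = s/(2-s).
    max_events : int
        Guard on the total number of simulated events per replicate before
        declaring coalescence unreachable.
    """

    samples: Sequence[int]
    sizes: Sequence[float] | None = None
    migration: float | Sequence[Sequence[float]] = 0.0
    selfing: float = 0.0
    recomb_rate: float = 0.0
    events: list[DemographicEvent] = field(default_factory=list)
    diploid: bool = False
    max_events: int = 10_000_000

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if not self.samples or any(s < 0 for s in self.samples):
            raise CoalescenceError("samples must be non-negative, one per population")
        if sum(self.samples) < 1:
            raise CoalescenceError("at least one sampled copy is required")
        npop = len(self.samples)
        if self.sizes is None:
            self.sizes = [1.0] * npop
        self.sizes = [float(x) for x in self.sizes]
        if len(self.sizes) != npop or any(x <= 0 for x in self.sizes):
            raise CoalescenceError("sizes must be positive, one per population")
        if not 0 <= self.selfing <= 1:
            raise CoalescenceError("selfing rate must be in [0, 1]")
        if self.recomb_rate < 0:
            raise CoalescenceError("recombination rate must be >= 0")
        self.migration = self._expand_migration(self.migration)
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def npop(self) -> int:
        return len(self.samples)

    @property
    def nleaves(self) -> int:
        mult = 2 if self.diploid else 1
        return mult * sum(self.samples)

    def _expand_migration(self, mig) -> np.ndarray:
        npop = self.npop
        if np.isscalar(mig):
            m = float(mig)
            if m < 0:
                raise CoalescenceError("migration rate must be >= 0")
            mat = np.full((npop, npop), m / (npop - 1) if npop > 1 else 0.0)
        else:
            mat = np.array(mig, dtype=float)
            if mat.shape != (npop, npop):
                raise CoalescenceError(
                    f"migration matrix must be {npop}x{npop}, got {mat.shape}"
                )
            if (mat < 0).any():
                raise CoalescenceError("migration rates must be >= 0")
        np.fill_diagonal(mat, 0.0)
        return mat

    def leaf_groups(self) -> list[int]:
        """Population label of each sampled gene copy, in leaf order."""
        mult = 2 if self.diploid else 1
        out = []
        for p, k in enumerate(self.samples):
            out.extend([p] * (mult * k))
        return out


@dataclass
class MutatorSpec:
    """Mutation side of the simulation.

    ``kind`` is one of ``infinite_site``, ``finite_allele``, ``stepwise`` or
    ``fixed_S``.  ``theta`` is 4N0*mu per locus (not used by ``fixed_S``,
    which places exactly ``fixed_S`` mutations).  ``finite_allele`` and
    ``stepwise`` evolve ``nsites`` markers at explicit ``positions`` in
    [0, 1) (evenly spaced when omitted); ``transition_weights`` is a square
    non-negative matrix with zero diagonal giving the relative probability
    of each mutational change (mutation bias).
    """

    kind: str = "infinite_site"
    theta: float = 0.0
    fixed_S: int | None = None
    nalleles: int = 4
    transition_weights: Sequence[Sequence[float]] | None = None
    nsites: int = 1
    positions: Sequence[float] | None = None

    KINDS = ("infinite_site", "finite_allele", "stepwise", "fixed_S")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise CoalescenceError(f"unknown mutator kind {self.kind!r}")
        if self.kind == "fixed_S":
            if self.fixed_S is None or self.fixed_S < 1:
                raise CoalescenceError("fixed_S requires fixed_S >= 1")
        else:
            if self.fixed_S is not None:
                raise CoalescenceError("fixed_S only valid with kind='fixed_S'")
            if self.theta < 0:
                raise CoalescenceError("theta must be >= 0")
        if self.kind in ("finite_allele", "stepwise"):
            if self.nsites < 1:
                raise CoalescenceError("nsites must be >= 1")
        if self.positions is not None:
            pos = list(self.positions)
            if any(not 0 <= x < 1 for x in pos):
                raise CoalescenceError("positions must lie in [0, 1)")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise CoalescenceError("positions must be strictly increasing")
            self.positions = pos
            self.nsites = len(pos)
        if self.kind == "finite_allele":
            if not 2 <= self.nalleles:
                raise CoalescenceError("finite_allele needs nalleles >= 2")
            if self.transition_weights is None:
                w = np.ones((self.nalleles, self.nalleles))
            else:
                w = np.array(self.transition_weights, dtype=float)
                if w.shape != (self.nalleles, self.nalleles):
                    raise CoalescenceError("transition_weights must be square "
                                           "of size nalleles")
                if (w < 0).any():
                    raise CoalescenceError("transition weights must be >= 0")
            np.fill_diagonal(w, 0.0)
            if (w.sum(axis=1) <= 0).any():
                raise CoalescenceError("each state needs a positive exit weight")
            self.transition_weights = w

    def marker_positions(self) -> list[float]:
        if self.positions is not None:
            return list(self.positions)
        return [(i + 0.5) / self.nsites for i in range(self.nsites)]


# ---------------------------------------------------------------------------
# ARG machinery
# ---------------------------------------------------------------------------

class _Node:
    """Genealogy node; its subtree is fixed within its creation interval."""

    __slots__ = ("height", "children", "leaf_id")

    def __init__(self, height: float, children=(), leaf_id: int | None = None):
        self.height = height
        self.children = tuple(children)
        self.leaf_id = leaf_id


class _Lineage:
    __slots__ = ("pop", "segments")

    def __init__(self, pop: int, segments: list[tuple[float, float, _Node]]):
        self.pop = pop
        self.segments = segments  # sorted, disjoint (left, right, node)

    @property
    def span(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]


class _CountMap:
    """Piecewise-constant count of lineages ancestral to each position."""

    def __init__(self, n: int):
        self.pos = [0.0]   # cell i covers [pos[i], pos[i+1]) (last ends at 1)
        self.cnt = [n]

    def _ensure(self, x: float) -> None:
        if x >= 1.0:
            return
        i = bisect_right(self.pos, x) - 1
        if self.pos[i] != x:
            self.pos.insert(i + 1, x)
            self.cnt.insert(i + 1, self.cnt[i])

    def decrement(self, left: float, right: float) -> list[tuple[float, float, int]]:
        """Subtract 1 over [left, right); return the affected cells
        as (a, b, new_count)."""
        self._ensure(left)
        self._ensure(right)
        i = bisect_right(self.pos, left) - 1
        out = []
        while i < len(self.pos) and self.pos[i] < right:
            a = self.pos[i]
            b = self.pos[i + 1] if i + 1 < len(self.pos) else 1.0
            self.cnt[i] -= 1
            out.append((a, b, self.cnt[i]))
            i += 1
        return out


def _sweep(seg1, seg2):
    """Partition the union of two segment lists into atomic pieces.

    Yields (left, right, node1 | None, node2 | None).
    """
    bounds = sorted({x for l, r, _ in seg1 for x in (l, r)} |
                    {x for l, r, _ in seg2 for x in (l, r)})

    def finder(segs):
        it = iter(segs)
        cur = next(it, None)

        def find(a):
            nonlocal cur
            while cur is not None and cur[1] <= a:
                cur = next(it, None)
            if cur is not None and cur[0] <= a < cur[1]:
                return cur[2]
            return None

        return find

    f1, f2 = finder(seg1), finder(seg2)
    for a, b in zip(bounds, bounds[1:]):
        n1, n2 = f1(a), f2(a)
        if n1 is not None or n2 is not None:
            yield a, b, n1, n2


class _Simulation:
    """One replicate of the structured ARG."""

    def __init__(self, model: DemographicModel, rng: np.random.Generator):
        self.model = model
        self.rng = rng
        self.npop = model.npop
        self.sizes = list(model.sizes)
        self.alphas = [0.0] * self.npop         # growth rates
        self.size_ref = list(model.sizes)       # size at last reference time
        self.t_ref = [0.0] * self.npop
        self.migration = model.migration.copy()
        self.selfing = model.selfing
        self.rho = model.recomb_rate
        self.t = 0.0
        self.mrcas: list[tuple[float, float, _Node]] = []
        n = model.nleaves
        self.counts = _CountMap(n)
        self.lineages: list[_Lineage] = []
        for leaf_id, pop in enumerate(model.leaf_groups()):
            node = _Node(0.0, leaf_id=leaf_id)
            self.lineages.append(_Lineage(pop, [(0.0, 1.0, node)]))
        self.n_events = 0
        if model.diploid:
            self._instant_selfing_coalescence()

    # -- setup ----------------------------------------------------------

    def _instant_selfing_coalescence(self) -> None:
        F = _selfing_factor(self.selfing) - 1.0
        # leaves come in within-individual pairs (0,1), (2,3), ...
        for i in range(0, len(self.model.leaf_groups()), 2):
            if self.rng.random() < F:
                a = next(l for l in self.lineages
                         if l.segments[0][2].leaf_id == i)
                b = next(l for l in self.lineages
                         if l.segments[0][2].leaf_id == i + 1)
                self._coalesce_pair(a, b)

    # -- population size under growth -----------------------------------

    def _size_at(self, pop: int, t: float) -> float:
        return self.size_ref[pop] * math.exp(-self.alphas[pop] * (t - self.t_ref[pop]))

    def _coal_waiting_time(self, pop: int, k: int) -> float:
        """Waiting time to the next coalescence in *pop* (inf if none)."""
        if k < 2:
            return math.inf
        C = k * (k - 1) * _selfing_factor(self.selfing)
        s_now = self._size_at(pop, self.t)
        E = self.rng.exponential()
        alpha = self.alphas[pop]
        if alpha == 0.0:
            return E * s_now / C
        arg = 1.0 + E * alpha * s_now / C
        if arg <= 0:
            return math.inf
        return math.log(arg) / alpha

    # -- event application ----------------------------------------------

    def _apply_event(self, ev: DemographicEvent) -> None:
        t = ev.time
        if isinstance(ev, SizeChange):
            self.size_ref[ev.pop] = ev.size
            self.t_ref[ev.pop] = t
            self.alphas[ev.pop] = 0.0
        elif isinstance(ev, GrowthChange):
            pops = range(self.npop) if ev.pop is None else [ev.pop]
            for p in pops:
                self.size_ref[p] = self._size_at(p, t)
                self.t_ref[p] = t
                self.alphas[p] = ev.alpha
        elif isinstance(ev, MigrationChange):
            if ev.matrix is not None:
                mat = np.array(ev.matrix, dtype=float)
                np.fill_diagonal(mat, 0.0)
                self.migration = mat
            else:
                m = float(ev.rate or 0.0)
                mat = np.full((self.npop, self.npop),
                              m / (self.npop - 1) if self.npop > 1 else 0.0)
                np.fill_diagonal(mat, 0.0)
                self.migration = mat
        elif isinstance(ev, PopulationMerge):
            for lin in self.lineages:
                if lin.pop == ev.source:
                    lin.pop = ev.dest
            self.migration[ev.source, :] = 0.0
            self.migration[:, ev.source] = 0.0
        elif isinstance(ev, Bottleneck):
            self._bottleneck(ev.pop, ev.strength)
        elif isinstance(ev, SelfingChange):
            self.selfing = ev.s
        else:  # pragma: no cover - defensive
            raise CoalescenceError(f"unknown event type {type(ev).__name__}")

    def _bottleneck(self, pop: int, strength: float) -> None:
        """Extra coalescent time at the event date, zero branch growth."""
        consumed = 0.0
        while True:
            members = [l for l in self.lineages if l.pop == pop]
            k = len(members)
            if k < 2:
                return
            w = self.rng.exponential(1.0 / (k * (k - 1)))
            consumed += w
            if consumed > strength:
                return
            i, j = self.rng.choice(k, size=2, replace=False)
            self._coalesce_pair(members[i], members[j])

    # -- core events -----------------------------------------------------

    def _coalesce_pair(self, x: _Lineage, y: _Lineage) -> None:
        t = self.t
        new_segments: list[tuple[float, float, _Node]] = []
        cache: dict[tuple[int, int], _Node] = {}
        for a, b, n1, n2 in _sweep(x.segments, y.segments):
            if n1 is None or n2 is None:
                new_segments.append((a, b, n1 if n1 is not None else n2))
                continue
            key = (id(n1), id(n2))
            parent = cache.get(key)
            if parent is None:
                parent = _Node(t, children=(n1, n2))
                cache[key] = parent
            for ca, cb, cnt in self.counts.decrement(a, b):
                if cnt <= 1:
                    self.mrcas.append((ca, cb, parent))
                else:
                    new_segments.append((ca, cb, parent))
        self.lineages.remove(x)
        self.lineages.remove(y)
        new_segments.sort(key=lambda s: s[0])
        if new_segments:
            self.lineages.append(_Lineage(x.pop, new_segments))

    def _recombine(self, lin: _Lineage) -> None:
        lmin = lin.segments[0][0]
        rmax = lin.segments[-1][1]
        x = self.rng.uniform(lmin, rmax)
        left, right = [], []
        for l, r, node in lin.segments:
            if r <= x:
                left.append((l, r, node))
            elif l >= x:
                right.append((l, r, node))
            else:
                left.append((l, x, node))
                right.append((x, r, node))
        if not left or not right:
            return  # breakpoint at a material boundary: no-op
        lin.segments = left
        self.lineages.append(_Lineage(lin.pop, right))

    # -- main loop --------------------------------------------------------

    def run(self) -> None:
        model = self.model
        events = list(model.events)
        ei = 0
        while len(self.lineages) >= 2:
            self.n_events += 1
            if self.n_events > model.max_events:
                raise UnreachableCoalescenceError(
                    "event guard exceeded: sample cannot coalesce "
                    "(isolated populations with no migration or merge event?)"
                )
            # candidate waiting times
            pops = [l.pop for l in self.lineages]
            kper = [pops.count(p) for p in range(self.npop)]
            w_coal = math.inf
            coal_pop = -1
            for p in range(self.npop):
                w = self._coal_waiting_time(p, kper[p])
                if w < w_coal:
                    w_coal, coal_pop = w, p
            mig_rates = np.array([self.migration[l.pop, :].sum()
                                  for l in self.lineages])
            mig_total = float(mig_rates.sum())
            w_mig = (self.rng.exponential(1.0 / mig_total)
                     if mig_total > 0 else math.inf)
            rec_rates = np.array([self.rho * l.span for l in self.lineages]) \
                if self.rho > 0 else np.zeros(len(self.lineages))
            rec_total = float(rec_rates.sum())
            w_rec = (self.rng.exponential(1.0 / rec_total)
                     if rec_total > 0 else math.inf)
            w_min = min(w_coal, w_mig, w_rec)
            if ei < len(events) and events[ei].time <= self.t + w_min:
                ev = events[ei]
                ei += 1
                self.t = ev.time
                self._apply_event(ev)
                continue
            if math.isinf(w_min):
                raise UnreachableCoalescenceError(
                    "no possible event: isolated populations with no "
                    "migration and no merge event"
                )
            self.t += w_min
            if w_min == w_coal:
                members = [l for l in self.lineages if l.pop == coal_pop]
                i, j = self.rng.choice(len(members), size=2, replace=False)
                self._coalesce_pair(members[i], members[j])
            elif w_min == w_mig:
                probs = mig_rates / mig_total
                li = self.rng.choice(len(self.lineages), p=probs)
                lin = self.lineages[li]
                row = self.migration[lin.pop, :]
                dest = self.rng.choice(self.npop, p=row / row.sum())
                lin.pop = int(dest)
            else:
                probs = rec_rates / rec_total
                li = self.rng.choice(len(self.lineages), p=probs)
                self._recombine(self.lineages[li])


# ---------------------------------------------------------------------------
# Genealogy container
# ---------------------------------------------------------------------------

@dataclass
class GenealogySet:
    """Marginal genealogies of one replicate: a partition of [0, 1).

    ``segments`` holds (left, right, root) triplets in locus order; each
    root spans the full sampled leaf count.
    """

    segments: list[tuple[float, float, _Node]]
    n_leaves: int
    leaf_groups: list[int]

    def n_trees(self) -> int:
        return len(self.segments)

    def tmrca(self, index: int = 0) -> float:
        return self.segments[index][2].height

    def total_length(self, index: int = 0) -> float:
        total = 0.0
        stack = [self.segments[index][2]]
        while stack:
            node = stack.pop()
            for c in node.children:
                total += node.height - c.height
                stack.append(c)
        return total

    def branches(self, index: int = 0) -> list[tuple[float, frozenset[int]]]:
        """(length, descendant leaf set) for every branch of one marginal tree."""
        root = self.segments[index][2]
        out = []

        def walk(node: _Node) -> frozenset[int]:
            if not node.children:
                return frozenset([node.leaf_id])
            acc = []
            for c in node.children:
                below = walk(c)
                out.append((node.height - c.height, below))
                acc.append(below)
            return frozenset().union(*acc)

        walk(root)
        return out

    def marginal_tree(self, index: int = 0) -> Tree:
        """Marginal genealogy as a :class:`seqdata.Tree` with branch lengths."""
        root = self.segments[index][2]

        def convert(node: _Node, parent_height: float | None) -> TreeNode:
            tn = TreeNode(
                label=f"s{node.leaf_id + 1}" if not node.children else None,
                length=(parent_height - node.height
                        if parent_height is not None else None),
            )
            tn.children = [convert(c, node.height) for c in node.children]
            return tn

        return Tree(convert(root, None))


def simulate_genealogy(
    model: DemographicModel,
    rng_seed: int | np.random.Generator,
) -> GenealogySet:
    """Simulate one ancestral recombination graph under *model*.

    Returns the partition of the unit locus into segments with their
    marginal genealogies.  Deterministic for a fixed (seed, parameters).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    sim = _Simulation(model, rng)
    n = model.nleaves
    if n == 1:
        node = sim.lineages[0].segments[0][2]
        return GenealogySet([(0.0, 1.0, node)], 1, model.leaf_groups())
    sim.run()
    segs = sorted(sim.mrcas, key=lambda s: s[0])
    # fuse adjacent intervals sharing the same marginal root
    fused: list[tuple[float, float, _Node]] = []
    for l, r, node in segs:
        if fused and fused[-1][2] is node and fused[-1][1] == l:
            fused[-1] = (fused[-1][0], r, node)
        else:
            fused.append((l, r, node))
    return GenealogySet(fused, n, model.leaf_groups())


# ---------------------------------------------------------------------------
# Mutators
# ---------------------------------------------------------------------------

@dataclass
class MicrosatMatrix:
    """Simulated microsatellite genotypes: copies x loci allele sizes."""

    alleles: np.ndarray
    groups: list[int]
    positions: list[float]


def _segment_branches(gen: GenealogySet):
    """Per segment: (left, right, [(length, leafset), ...], total length)."""
    out = []
    for idx, (l, r, _) in enumerate(gen.segments):
        branches = gen.branches(idx)
        total = sum(b[0] for b in branches)
        out.append((l, r, branches, total))
    return out


def _alignment_from_columns(
    columns: list[tuple[float, np.ndarray]],
    gen: GenealogySet,
    ancestral_row: str | None = None,
) -> Alignment:
    """Build an Alignment from (position, column-characters) pairs."""
    columns.sort(key=lambda c: c[0])
    n = gen.n_leaves
    if columns:
        mat = np.stack([col for _, col in columns], axis=1)
        seqs = ["".join(row) for row in mat]
    else:
        seqs = [""] * n
    entries = [
        SequenceEntry(name=f"s{i + 1}", sequence=seqs[i],
                      group=gen.leaf_groups[i])
        for i in range(n)
    ]
    if ancestral_row is not None:
        entries.append(
            SequenceEntry(name="outgroup", sequence=ancestral_row,
                          group=0, is_outgroup=True)
        )
    aln = Alignment(entries)
    aln.positions = [pos for pos, _ in columns]  # type: ignore[attr-defined]
    return aln


def _binary_column(n: int, leafset: frozenset[int]) -> np.ndarray:
    col = np.full(n, "A", dtype="U1")
    col[list(leafset)] = "T"
    return col


def apply_mutator(
    gen: GenealogySet,
    mut: MutatorSpec,
    rng_seed: int | np.random.Generator,
    outgroup: bool = False,
):
    """Drop mutations on a genealogy and return the simulated data.

    Nucleotide mutators return an :class:`Alignment` (with an all-ancestral
    outgroup row when *outgroup* is requested); ``stepwise`` returns a
    :class:`MicrosatMatrix`.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if mut.kind == "infinite_site":
        return _mutate_infinite(gen, mut.theta, None, rng, outgroup)
    if mut.kind == "fixed_S":
        return _mutate_infinite(gen, None, mut.fixed_S, rng, outgroup)
    if mut.kind == "finite_allele":
        return _mutate_finite(gen, mut, rng, outgroup)
    if mut.kind == "stepwise":
        return _mutate_stepwise(gen, mut, rng)
    raise CoalescenceError(f"unknown mutator kind {mut.kind!r}")


def _mutate_infinite(gen, theta, fixed_S, rng, outgroup) -> Alignment:
    n = gen.n_leaves
    seg_info = _segment_branches(gen)
    # weight of each (segment, branch): width * branch length
    weights = []
    flat = []
    for l, r, branches, _ in seg_info:
        for length, leafset in branches:
            weights.append((r - l) * length)
            flat.append((l, r, leafset))
    weights = np.array(weights) if weights else np.zeros(0)
    total = float(weights.sum())
    if fixed_S is not None:
        if total <= 0:
            raise CoalescenceError(
                "fixed_S mutator needs a genealogy with positive length")
        nmut = fixed_S
    else:
        nmut = int(rng.poisson(theta * total)) if total > 0 and theta > 0 else 0
    columns: list[tuple[float, np.ndarray]] = []
    if nmut:
        idx = rng.choice(len(flat), size=nmut, p=weights / total)
        for i in idx:
            l, r, leafset = flat[i]
            pos = float(rng.uniform(l, r))
            columns.append((pos, _binary_column(n, leafset)))
    anc = "A" * nmut if outgroup else None
    return _alignment_from_columns(columns, gen, anc)


def _stationary(weights: np.ndarray) -> np.ndarray:
    """Stationary distribution of the row-normalised jump chain."""
    P = weights / weights.sum(axis=1, keepdims=True)
    k = P.shape[0]
    A = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / pi.sum()


_STATE_LETTERS = "ACGT"


def _evolve_site(root, n, rate, start_state, step, rng) -> np.ndarray:
    """Evolve one marker down a marginal tree; *step* maps (state, k) to a
    new state after k mutation events."""
    states = np.zeros(n, dtype=int)

    def walk(node, state):
        for c in node.children:
            length = node.height - c.height
            k = rng.poisson(rate * length)
            child_state = step(state, k) if k else state
            if c.children:
                walk(c, child_state)
            else:
                states[c.leaf_id] = child_state

    if root.children:
        walk(root, start_state)
    else:
        states[root.leaf_id] = start_state
    return states


def _find_segment(gen: GenealogySet, pos: float):
    for idx, (l, r, _) in enumerate(gen.segments):
        if l <= pos < r:
            return idx
    return len(gen.segments) - 1


def _mutate_finite(gen, mut: MutatorSpec, rng, outgroup) -> Alignment:
    n = gen.n_leaves
    if mut.nalleles > 4:
        raise CoalescenceError(
            "finite_allele with nucleotide output needs nalleles <= 4")
    W = np.asarray(mut.transition_weights, dtype=float)
    P = W / W.sum(axis=1, keepdims=True)
    pi = _stationary(W)
    positions = mut.marker_positions()
    rate = mut.theta / len(positions)

    def step(state, k):
        s = state
        for _ in range(k):
            s = int(rng.choice(mut.nalleles, p=P[s]))
        return s

    columns = []
    ancestral = []
    for pos in positions:
        idx = _find_segment(gen, pos)
        root = gen.segments[idx][2]
        start = int(rng.choice(mut.nalleles, p=pi))
        states = _evolve_site(root, n, rate, start, step, rng)
        col = np.array([_STATE_LETTERS[s] for s in states], dtype="U1")
        columns.append((pos, col))
        ancestral.append(_STATE_LETTERS[start])
    anc = "".join(ancestral) if outgroup else None
    return _alignment_from_columns(columns, gen, anc)


def _mutate_stepwise(gen, mut: MutatorSpec, rng) -> MicrosatMatrix:
    n = gen.n_leaves
    positions = mut.marker_positions()
    rate = mut.theta / len(positions)

    def step(state, k):
        return state + int(np.sum(rng.choice((-1, 1), size=k)))

    cols = []
    for pos in positions:
        idx = _find_segment(gen, pos)
        root = gen.segments[idx][2]
        cols.append(_evolve_site(root, n, rate, 0, step, rng))
    return MicrosatMatrix(
        alleles=np.stack(cols, axis=1),
        groups=gen.leaf_groups,
        positions=positions,
    )


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def coalesce(
    model: DemographicModel,
    mut: MutatorSpec,
    nrepets: int,
    rng_seed: int | np.random.Generator = 0,
    outgroup: bool = False,
) -> list:
    """Simulate *nrepets* independent replicates: genealogy + mutations.

    Returns a list of :class:`Alignment` (or :class:`MicrosatMatrix` for the
    stepwise mutator); rows carry group labels matching the sampling
    configuration, plus an ancestral ``outgroup`` row when requested.
    Deterministic under a fixed seed.
    """
    if nrepets < 1:
        raise CoalescenceError("nrepets must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    out = []
    for _ in range(nrepets):
        gen = simulate_genealogy(model, rng)
        out.append(apply_mutator(gen, mut, rng, outgroup=outgroup))
    return out


# ---------------------------------------------------------------------------
# Vectorised single-population kernel (unfolded SFS)
# ---------------------------------------------------------------------------

def simulate_sfs_batch(
    n: int,
    thetas: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unfolded site-frequency spectra for a batch of neutral replicates.

    Simulates the standard single-population constant-size coalescent for a
    sample of *n* gene copies, one replicate per entry of *thetas*
    (per-locus 4N0*mu), fully vectorised across replicates.  Returns an
    integer array of shape (len(thetas), n - 1): column d-1 counts mutations
    at derived frequency d.  This is the fast path used for bulk simulation
    in ABC; it is statistically equivalent to the generic simulator at
    rho = 0 with an infinite-site mutator.
    """
    thetas = np.asarray(thetas, dtype=float)
    R = thetas.size
    if n < 2:
        raise CoalescenceError("need n >= 2")
    desc = np.ones((R, n), dtype=np.int64)
    birth = np.zeros((R, n))
    xi = np.zeros((R, n), dtype=np.int64)
    t = np.zeros(R)
    rows = np.arange(R)
    for k in range(n, 1, -1):
        t = t + rng.exponential(1.0 / (k * (k - 1)), size=R)
        a = rng.integers(0, k, size=R)
        b = rng.integers(0, k - 1, size=R)
        b = b + (b >= a)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        d_lo = desc[rows, lo]
        d_hi = desc[rows, hi]
        m_lo = rng.poisson(thetas * (t - birth[rows, lo]))
        m_hi = rng.poisson(thetas * (t - birth[rows, hi]))
        np.add.at(xi, (rows, d_lo), m_lo)
        np.add.at(xi, (rows, d_hi), m_hi)
        desc[rows, lo] = d_lo + d_hi
        birth[rows, lo] = t
        desc[rows, hi] = desc[rows, k - 1]
        birth[rows, hi] = birth[rows, k - 1]
    return xi[:, 1:n]
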
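"""Helix assembly and secondary/tertiary topology classification.

A helix is a continuous base-paired stack faithful to strand connectivity:
consecutive pairs (i,j), (i',j') belong to the same helix when the 5'
indices ascend, the 3' indices descend, the sequence gaps on both strands
stay within the bulge tolerance, and a stacking contact bridges the
junction.  Bulges and non-canonical pairs do not break a helix as long as
the stack is unbroken.  Each nucleotide belongs to at most one helix;
pairs inside helices are secondary interactions, all remaining pairs
(lone pairs, demoted base-triple partners) are tertiary.

Two helices cross when a pair (i,q) of one and a pair (j,p) of the other
interleave as i < j < q < p.  The secondary structure proper is the
maximum-weight crossing-free subset of helices (weight = number of pairs),
found by exact search; crossing helices left over are pseudoknotted /
kissing-loop elements stacked into additional layers.  A configured list
of forced-secondary helix labels supports the convention of drawing the
SSU central pseudoknot helix as a secondary element even though it is
non-nested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .pair_geometry import BasePair, StackContact

logger = logging.getLogger(__name__)

__all__ = [
    "Helix",
    "TopologyAnnotation",
    "DomainScheme",
    "DomainSchemeError",
    "InfeasibleConstraintError",
    "assemble_helices",
    "enforce_unique_membership",
    "classify_pair_roles",
    "classify_nesting",
    "decompose_triples",
    "assign_domains",
    "apply_helix_labels",
    "helices_cross",
]

NESTED_SECONDARY = "nested_secondary"
NON_NESTED_TERTIARY = "non_nested_tertiary"
FORCED_SECONDARY = "forced_secondary"

SECONDARY = "secondary"
TERTIARY = "tertiary"


class InfeasibleConstraintError(Exception):
    """Mutually crossing helices were both forced into the nested set."""


class DomainSchemeError(Exception):
    """Invalid domain-scheme configuration (overlapping or bad ranges)."""


@dataclass
class Helix:
    """An ordered, continuous base-paired stack.

    ``pairs`` are ordered so 5'-strand indices ascend and 3'-strand
    indices descend.  ``has_defect`` marks helices whose stack bridges a
    bulge or other sequence-level interruption.
    """

    helix_id: int
    pairs: list[BasePair]
    has_defect: bool = False
    label: str | None = None

    @property
    def strand5_range(self) -> tuple[int, int]:
        return (self.pairs[0].i, self.pairs[-1].i)

    @property
    def strand3_range(self) -> tuple[int, int]:
        return (self.pairs[-1].j, self.pairs[0].j)

    @property
    def weight(self) -> int:
        return len(self.pairs)

    def residues(self) -> set[int]:
        out: set[int] = set()
        for p in self.pairs:
            out.add(p.i)
            out.add(p.j)
        return out

    def validate(self) -> None:
        assert self.pairs, "helix must contain at least one pair"
        for a, b in zip(self.pairs, self.pairs[1:]):
            assert a.i < b.i and b.j < a.j, "strand connectivity violated"
        seen: set[int] = set()
        for p in self.pairs:
            assert p.i not in seen and p.j not in seen, "residue repeated in helix"
            seen.update((p.i, p.j))


@dataclass
class TopologyAnnotation:
    """Topology classification of helices and pairs.

    ``layer`` 0 is the nested secondary set; layers 1, 2, ... hold
    mutually non-crossing groups of pseudoknotted helices.
    """

    helix_class: dict[int, str] = field(default_factory=dict)
    layer: dict[int, int] = field(default_factory=dict)
    pair_role: dict[tuple[int, int], str] = field(default_factory=dict)
    crossing_pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class DomainScheme:
    """Named, colored, non-overlapping residue-index ranges (1-based)."""

    domains: list[tuple[str, str, list[tuple[int, int]]]] = field(default_factory=list)

    def validate(self) -> None:
        covered: list[tuple[int, int, str]] = []
        for name, _color, ranges in self.domains:
            for lo, hi in ranges:
                if lo < 1 or hi < lo:
                    raise DomainSchemeError(f"domain {name}: bad range {lo}-{hi}")
                for plo, phi, pname in covered:
                    if lo <= phi and plo <= hi:
                        raise DomainSchemeError(
                            f"domain ranges overlap: {pname} {plo}-{phi} vs {name} {lo}-{hi}"
                        )
                covered.append((lo, hi, name))


def _chainable(
    a: BasePair,
    b: BasePair,
    g: int,
    stack_keys: frozenset[tuple[int, int]] | None,
) -> bool:
    """True when pair b continues the stack started by pair a."""
    if not (a.i < b.i <= a.i + 1 + g):
        return False
    if not (b.j < a.j <= b.j + 1 + g):
        return False
    if stack_keys is None:  # pairing-list-only mode: strict adjacency
        return b.i == a.i + 1 and a.j == b.j + 1
    return (a.i, b.i) in stack_keys or (b.j, a.j) in stack_keys


def assemble_helices(
    pairs: list[BasePair],
    stacks: list[StackContact],
    n_residues: int,
    g: int = 3,
) -> list[Helix]:
    """Chain base pairs into maximal continuous stacks.

    ``g`` is the bulge tolerance: the number of unpaired nucleotides a
    strand may skip between consecutive pairs, provided a stacking contact
    bridges the junction (geometry, not sequence gap, is the criterion).
    With an empty ``stacks`` list the function operates in
    pairing-list-only mode, where strict sequence adjacency substitutes
    for the stacking requirement.  Non-canonical pairs chain exactly like
    canonical ones.  Lone pairs become 1-pair helices.
    """
    for p in pairs:
        if not (1 <= p.i < p.j <= n_residues):
            raise ValueError(f"pair ({p.i},{p.j}) outside 1..{n_residues}")
    stack_keys = (
        frozenset((s.i, s.j) for s in stacks) if stacks else None
    )
    ordered = sorted(pairs, key=lambda p: (p.i, p.j))
    unused = set(range(len(ordered)))
    helices: list[Helix] = []
    for start in range(len(ordered)):
        if start not in unused:
            continue
        unused.discard(start)
        chain = [ordered[start]]
        used_res = {ordered[start].i, ordered[start].j}
        while True:
            last = chain[-1]
            best_k = None
            for k in sorted(unused):
                cand = ordered[k]
                if cand.i > last.i + 1 + g:
                    break
                if cand.i in used_res or cand.j in used_res:
                    continue
                if _chainable(last, cand, g, stack_keys):
                    # prefer tightest continuation: smallest i', then largest j'
                    if best_k is None or (
                        (cand.i, -cand.j) < (ordered[best_k].i, -ordered[best_k].j)
                    ):
                        best_k = k
            if best_k is None:
                break
            unused.discard(best_k)
            chain.append(ordered[best_k])
            used_res.update((ordered[best_k].i, ordered[best_k].j))
        has_defect = any(
            b.i > a.i + 1 or a.j > b.j + 1 for a, b in zip(chain, chain[1:])
        )
        helices.append(Helix(helix_id=len(helices) + 1, pairs=chain, has_defect=has_defect))
    for h in helices:
        h.validate()
    return helices


def _renumber(helices: list[Helix]) -> list[Helix]:
    helices.sort(key=lambda h: (h.strand5_range[0], h.strand3_range[0]))
    for idx, h in enumerate(helices, start=1):
        h.helix_id = idx
    return helices


def _split_on_break(helix: Helix) -> list[list[BasePair]]:
    """Split a helix whose pairs lost continuity after a demotion."""
    runs: list[list[BasePair]] = [[helix.pairs[0]]]
    for prev, cur in zip(helix.pairs, helix.pairs[1:]):
        if prev.i < cur.i and cur.j < prev.j:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    return runs


def enforce_unique_membership(
    helices: list[Helix],
    all_pairs: list[BasePair],
) -> tuple[list[Helix], list[BasePair]]:
    """Resolve residues claimed by pairs of two different helices.

    When a base triple spans two helices, the pair belonging to the longer
    helix (more pairs; ties broken toward the helix starting earlier on
    the 5' strand, then earlier on the 3' strand) keeps its membership;
    the competing pair is removed from its helix and returned as demoted.
    Demoted pairs remain pairs and are later classified tertiary.
    Idempotent: a second application changes nothing.
    """
    # rank: better (kept) helix sorts first
    def rank(h: Helix) -> tuple[int, int, int]:
        return (-h.weight, h.strand5_range[0], h.strand3_range[0])

    demoted: list[BasePair] = []
    changed = True
    while changed:
        changed = False
        owner: dict[int, Helix] = {}
        for h in sorted(helices, key=rank):
            drop: list[BasePair] = []
            for p in h.pairs:
                if (p.i in owner and owner[p.i] is not h) or (
                    p.j in owner and owner[p.j] is not h
                ):
                    drop.append(p)
                else:
                    owner[p.i] = h
                    owner[p.j] = h
            if drop:
                changed = True
                demoted.extend(drop)
                h.pairs = [p for p in h.pairs if p not in drop]
        survivors: list[Helix] = []
        for h in helices:
            if not h.pairs:
                continue
            runs = _split_on_break(h)
            for run in runs:
                survivors.append(Helix(helix_id=0, pairs=run, has_defect=any(
                    b.i > a.i + 1 or a.j > b.j + 1 for a, b in zip(run, run[1:])
                ), label=h.label))
        helices = survivors
    helices = _renumber(helices)
    for h in helices:
        h.validate()
    if demoted:
        logger.info("%d pair(s) demoted to tertiary by unique-membership rule", len(demoted))
    demoted.sort(key=lambda p: (p.i, p.j))
    return helices, demoted


def classify_pair_roles(
    helices: list[Helix],
    all_pairs: list[BasePair],
    annotation: TopologyAnnotation | None = None,
) -> TopologyAnnotation:
    """Pairs inside helical regions are secondary; all others tertiary.

    Non-canonical pairs internal to or extending a helix are therefore
    secondary; lone pairs and demoted triple partners are tertiary.  A
    single isolated pair is kept as a 1-pair Helix object for bookkeeping
    but does not constitute a helical region, so its pair is tertiary.
    """
    ann = annotation or TopologyAnnotation()
    in_helix = {p.key() for h in helices if h.weight >= 2 for p in h.pairs}
    for p in all_pairs:
        ann.pair_role[p.key()] = SECONDARY if p.key() in in_helix else TERTIARY
    return ann


def helices_cross(a: Helix, b: Helix) -> bool:
    """True when some pair of a and some pair of b interleave i<j<q<p."""
    for pa in a.pairs:
        for pb in b.pairs:
            i, q = pa.i, pa.j
            j, p = pb.i, pb.j
            if i < j < q < p or j < i < p < q:
                return True
    return False


def _components(n: int, adj: list[set[int]]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for v in range(n):
        if v in seen:
            continue
        stack, comp = [v], []
        seen.add(v)
        while stack:
            u = stack.pop()
            comp.append(u)
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _max_weight_independent_set(
    verts: list[int],
    adj: list[set[int]],
    weight: dict[int, int],
    start_key: dict[int, int],
) -> set[int]:
    """Exact maximum-weight independent set on one crossing-graph component.

    Ties in total weight are broken toward the subset whose sorted list of
    5'-strand starts is lexicographically smallest, so the selection is
    fully deterministic.
    """
    order = sorted(verts, key=lambda v: (start_key[v], v))
    best: tuple[int, tuple[int, ...], frozenset[int]] | None = None

    def tie_key(sel: list[int]) -> tuple[int, ...]:
        return tuple(sorted(start_key[v] for v in sel))

    def rec(idx: int, chosen: list[int], blocked: set[int], cur_w: int, rest_w: int) -> None:
        nonlocal best
        if best is not None and cur_w + rest_w < best[0]:
            return
        if idx == len(order):
            cand = (cur_w, tie_key(chosen), frozenset(chosen))
            if best is None or (cand[0], tuple(-k for k in cand[1])) > (
                best[0], tuple(-k for k in best[1])
            ):
                best = cand
            return
        v = order[idx]
        rest = rest_w - weight[v]
        if v not in blocked:
            rec(idx + 1, chosen + [v], blocked | adj[v], cur_w + weight[v], rest)
        rec(idx + 1, chosen, blocked, cur_w, rest)

    rec(0, [], set(), 0, sum(weight[v] for v in order))
    assert best is not None
    return set(best[2])


def classify_nesting(
    helices: list[Helix],
    forced_secondary: list[str] | None = None,
    annotation: TopologyAnnotation | None = None,
) -> TopologyAnnotation:
    """Split helices into the nested layer-0 set and pseudoknot layers.

    Layer 0 is the maximum-weight crossing-free subset (weight = pair
    count), found by exact search per connected component of the crossing
    graph.  Helices whose label appears in ``forced_secondary`` are
    constrained into layer 0 (class ``forced_secondary``); any helix
    crossing a forced helix is excluded from layer 0 regardless of weight.
    Remaining helices are assigned greedily, in order of descending
    weight, to the lowest layer >= 1 where they cross nothing.
    """
    ann = annotation or TopologyAnnotation()
    forced_labels = set(forced_secondary or [])
    n = len(helices)
    ids = [h.helix_id for h in helices]
    adj: list[set[int]] = [set() for _ in range(n)]
    for a in range(n):
        for b in range(a + 1, n):
            if helices_cross(helices[a], helices[b]):
                adj[a].add(b)
                adj[b].add(a)
                ann.crossing_pairs.append((ids[a], ids[b]))

    forced_idx = {
        k for k, h in enumerate(helices) if h.label is not None and h.label in forced_labels
    }
    for a in forced_idx:
        for b in forced_idx:
            if b in adj[a]:
                raise InfeasibleConstraintError(
                    f"forced-secondary helices {helices[a].label!r} and "
                    f"{helices[b].label!r} cross each other"
                )

    banned = {k for a in forced_idx for k in adj[a]}
    free = [k for k in range(n) if k not in forced_idx and k not in banned]
    weight = {k: helices[k].weight for k in range(n)}
    start_key = {k: helices[k].strand5_range[0] for k in range(n)}

    selected: set[int] = set(forced_idx)
    free_set = set(free)
    sub_adj = [adj[k] & free_set for k in range(n)]
    for comp in _components(n, [a & free_set for a in adj]):
        comp = [v for v in comp if v in free_set]
        if not comp:
            continue
        selected |= _max_weight_independent_set(comp, sub_adj, weight, start_key)

    for k in range(n):
        hid = ids[k]
        if k in selected:
            ann.layer[hid] = 0
            ann.helix_class[hid] = (
                FORCED_SECONDARY if k in forced_idx else NESTED_SECONDARY
            )
    leftovers = sorted(
        (k for k in range(n) if k not in selected),
        key=lambda k: (-weight[k], start_key[k]),
    )
    layers: list[list[int]] = []
    for k in leftovers:
        placed = False
        for li, members in enumerate(layers, start=1):
            if not any(m in adj[k] for m in members):
                members.append(k)
                ann.layer[ids[k]] = li
                placed = True
                break
        if not placed:
            layers.append([k])
            ann.layer[ids[k]] = len(layers)
        ann.helix_class[ids[k]] = NON_NESTED_TERTIARY
    return ann


def decompose_triples(
    all_pairs: list[BasePair],
    annotation: TopologyAnnotation,
    n_residues: int,
) -> dict[int, list[int]]:
    """Per-residue ordered partner lists; base triples become pairs of pairs.

    Slot 0 holds the secondary (helix) partner when one exists; additional
    partners follow in ascending index order.  No pairing information is
    dropped: a triple of residues connected by two pairs appears as
    exactly those two pairs.
    """
    partners: dict[int, list[int]] = {r: [] for r in range(1, n_residues + 1)}
    sec: dict[int, list[int]] = {}
    extra: dict[int, list[int]] = {}
    for p in all_pairs:
        role = annotation.pair_role.get(p.key(), TERTIARY)
        for a, b in ((p.i, p.j), (p.j, p.i)):
            (sec if role == SECONDARY else extra).setdefault(a, []).append(b)
    for r in range(1, n_residues + 1):
        slot = sorted(sec.get(r, [])) + sorted(extra.get(r, []))
        partners[r] = slot
        if len(slot) > 3:
            logger.warning(
                "residue %d participates in %d pairs; structural anomaly retained",
                r, len(slot),
            )
    return partners


def assign_domains(n_residues: int, scheme: DomainScheme) -> list[str]:
    """Label each residue with its domain name, or "unassigned"."""
    scheme.validate()
    labels = ["unassigned"] * n_residues
    for name, _color, ranges in scheme.domains:
        for lo, hi in ranges:
            if hi > n_residues:
                raise DomainSchemeError(
                    f"domain {name}: range {lo}-{hi} exceeds {n_residues} residues"
                )
            for r in range(lo, hi + 1):
                labels[r - 1] = name
    return labels


def apply_helix_labels(
    helices: list[Helix],
    label_ranges: dict[str, tuple[int, int]],
) -> None:
    """Attach user-supplied names to helices by 5'-strand range containment."""
    for h in helices:
        lo, hi = h.strand5_range
        for name, (rlo, rhi) in label_ranges.items():
            if rlo <= lo and hi <= rhi:
                h.label = name
                break
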
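"""Decomposition of the assembly graph into circular chromosomes, subgenome
merging, shared-repeat detection and master-circle hypotheses.

The decomposition follows a parsimony rule: every contig appears at least
once, no contig appears more often than its depth-estimated copy number, and
the total genome length is minimal among link-compatible cycle covers.  The
cover is found in two passes:

* a **main pass** over full-stoichiometry contigs, solved exactly as a small
  integer program (contig multiplicities and link-use counts; ties broken
  toward higher total link support), followed by an exhaustive (or, past a
  configurable size, greedy seeded-restart) choice of junction pairings that
  maximises the number of separate circles — the subdivided molecules are
  the primary presentation, as in the underlying biology where subgenomic
  circles coexist with their fused forms;
* a **substoichiometric pass** that closes minor-configuration circles
  through the depth-flagged contigs, borrowing full-stoichiometry backbone
  contigs where the evidence requires it.  These circles carry an abundance
  tag and their length does not enter the main parsimony objective.

Circles sharing a multi-copy contig are merged transitively into subgenomes;
the merged circular sequence is produced by repeat-mediated insertion, which
preserves every junction of every member circle (both repeat copies are
retained, one per former junction).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from ._seq import gc_fraction, revcomp
from .graph import HEAD, TAIL, AssemblyGraph, End, Link

MAX_BORROW = 2  # extra uses of a backbone contig allowed in the substoich pass


class StructureError(ValueError):
    """No link-compatible cycle cover exists."""


class OrientedContig(NamedTuple):
    id: str
    orientation: str  # '+' or '-'

    def flipped(self) -> "OrientedContig":
        return OrientedContig(self.id, "-" if self.orientation == "+" else "+")

    def __str__(self) -> str:
        return f"{self.id}{self.orientation}"


Order = tuple[OrientedContig, ...]


def order_string(order: Sequence[OrientedContig]) -> str:
    return ",".join(str(oc) for oc in order)


def reverse_order(order: Sequence[OrientedContig]) -> Order:
    """The same circle traversed in the opposite direction."""
    return tuple(oc.flipped() for oc in reversed(order))


def canonical_order(order: Sequence[OrientedContig]) -> Order:
    """Rotation/reflection-canonical form: start at the lexicographically
    smallest contig id in '+' orientation (its '−' occurrence if '+' never
    occurs), choosing the traversal direction with the smaller order string."""
    candidates: list[Order] = []
    for base in (tuple(order), reverse_order(order)):
        for i in range(len(base)):
            candidates.append(base[i:] + base[:i])
    min_id = min(oc.id for oc in order)
    starts = [c for c in candidates if c[0] == OrientedContig(min_id, "+")]
    if not starts:
        starts = [c for c in candidates if c[0].id == min_id]
    return min(starts, key=order_string)


@dataclass
class CircularChromosome:
    """An ordered, oriented, rotation/reflection-canonical contig cycle."""
    id: str
    order: Order
    support: int
    length: int
    abundance: float | None = None  # set for substoichiometric molecules

    @property
    def contig_ids(self) -> set[str]:
        return {oc.id for oc in self.order}

    def sequence(self, contigs) -> str:
        return "".join(
            contigs[oc.id].seq if oc.orientation == "+" else revcomp(contigs[oc.id].seq)
            for oc in self.order)


@dataclass
class RepeatMatch:
    molecule_a: str
    start_a: int
    molecule_b: str
    start_b: int
    length: int
    identity: float
    orientation: str  # 'direct' | 'inverted'


@dataclass
class MasterCircleHypothesis:
    """A predicted recombinant joining two subgenomes at a shared repeat.

    A prediction only — never promoted to a subgenome.  Single reciprocal
    crossover at the repeat: both copies are retained, one per former
    junction, so the recombinant length is the sum of the two subgenomes.
    """
    subgenome_a: str
    subgenome_b: str
    match: RepeatMatch
    length: int
    sequence: str


@dataclass
class Subgenome:
    id: str
    circle_ids: list[str]
    order: Order
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OrderAlternative:
    circle_id: str
    primary: str
    alternative: str
    primary_support: int
    alternative_support: int
    tie: bool

    @property
    def support_ratio(self) -> float:
        if self.primary_support == 0:
            return 1.0
        return self.alternative_support / self.primary_support


@dataclass
class GenomeStructure:
    circles: list[CircularChromosome]
    plasmids: list[tuple[str, str]]  # (id, sequence), numbered by length
    merge_events: list[tuple[tuple[str, str], str]]
    subgenomes: list[Subgenome]
    master_hypotheses: list[MasterCircleHypothesis] = field(default_factory=list)
    ambiguous_orders: list[OrderAlternative] = field(default_factory=list)
    linear_candidates: list[list[str]] = field(default_factory=list)
    search_mode: str = "exact"

    def circle(self, cid: str) -> CircularChromosome:
        return next(c for c in self.circles if c.id == cid)


# --------------------------------------------------------------------------
# cycle cover

def _end_exit(oc: OrientedContig) -> End:
    return (oc.id, TAIL if oc.orientation == "+" else HEAD)


def _end_entry(oc: OrientedContig) -> End:
    return (oc.id, HEAD if oc.orientation == "+" else TAIL)


def junction_ends(a: OrientedContig, b: OrientedContig) -> tuple[End, End]:
    """The unordered link end pair realised by the adjacency a→b."""
    pair = sorted([_end_exit(a), _end_entry(b)])
    return (pair[0], pair[1])


def _solve_cover_milp(lengths: dict[str, int], caps: dict[str, int],
                      lower: dict[str, int], links: list[Link],
                      ) -> tuple[dict[str, int], dict[int, int]] | None:
    """Choose contig multiplicities m and link-use counts t minimising
    Σ len·m, ties broken toward higher total used link support.

    Per contig end: Σ uses of incident links (a self-link closing on one end
    counts twice there) equals the contig's multiplicity.  Returns None if
    infeasible.
    """
    ids = sorted(lengths)
    idx = {cid: i for i, cid in enumerate(ids)}
    n_m, n_t = len(ids), len(links)
    ub_t = max(caps.values(), default=1) + MAX_BORROW

    rows = []
    for cid in ids:
        for side in (HEAD, TAIL):
            row = np.zeros(n_m + n_t)
            row[idx[cid]] = -1.0
            for j, l in enumerate(links):
                row[n_m + j] += l.touches((cid, side))
            rows.append(row)

    # support tie-break strictly below the smallest length step (1 bp)
    eps = 0.5 / (sum(l.support for l in links) * ub_t + 1)
    c = np.array([float(lengths[cid]) for cid in ids]
                 + [-eps * l.support for l in links])
    lb = np.array([float(lower[cid]) for cid in ids] + [0.0] * n_t)
    ub = np.array([float(caps[cid]) for cid in ids] + [float(ub_t)] * n_t)

    constraints = ([LinearConstraint(np.array(rows), 0.0, 0.0)] if rows else [])
    res = milp(c=c, constraints=constraints,
               integrality=np.ones(n_m + n_t), bounds=Bounds(lb, ub))
    if not res.success:
        return None
    x = np.round(res.x).astype(int)
    m = {cid: int(x[idx[cid]]) for cid in ids}
    t = {j: int(x[n_m + j]) for j in range(n_t) if x[n_m + j] > 0}
    return m, t


def _build_slots(m: dict[str, int], t: dict[int, int], links: list[Link],
                 ) -> dict[str, dict[str, list[tuple[int, int, str]]]]:
    slots: dict[str, dict[str, list[tuple[int, int, str]]]] = {
        cid: {HEAD: [], TAIL: []} for cid, mm in m.items() if mm > 0}
    for j in sorted(t):
        l = links[j]
        for u in range(t[j]):
            for tag, end in (("a", l.end_a), ("b", l.end_b)):
                slots[end[0]][end[1]].append((j, u, tag))
    return slots


def _trace_cycles(m: dict[str, int], t: dict[int, int], links: list[Link],
                  pairing: dict[str, tuple[int, ...]],
                  slots: dict[str, dict[str, list[tuple[int, int, str]]]],
                  ) -> list[tuple[Order, int]]:
    """Trace circles given multiplicities, link uses and per-contig pairings.

    Contig instance ``i`` owns H-slot position ``i`` and T-slot position
    ``pairing[cid][i]``.  Entering an instance at its head reads '+',
    at its tail '−'.
    """
    owner: dict[tuple[int, int, str], tuple[str, int, str]] = {}
    for cid, sides in slots.items():
        for i, ep in enumerate(sides[HEAD]):
            owner[ep] = (cid, i, HEAD)
        for pos, ep in enumerate(sides[TAIL]):
            owner[ep] = (cid, pairing[cid].index(pos), TAIL)

    mate: dict[tuple[int, int, str], tuple[int, int, str]] = {}
    for j, uses in t.items():
        for u in range(uses):
            mate[(j, u, "a")] = (j, u, "b")
            mate[(j, u, "b")] = (j, u, "a")

    def instance_exit(cid: str, inst: int, entered_side: str):
        if entered_side == HEAD:
            return slots[cid][TAIL][pairing[cid][inst]]
        return slots[cid][HEAD][inst]

    visited: set[tuple[str, int]] = set()
    cycles: list[tuple[Order, int]] = []
    for cid in sorted(slots):
        for inst in range(m[cid]):
            if (cid, inst) in visited:
                continue
            order: list[OrientedContig] = []
            supports: list[int] = []
            cur, cur_inst, entry_side = cid, inst, HEAD
            while True:
                visited.add((cur, cur_inst))
                order.append(OrientedContig(cur, "+" if entry_side == HEAD else "-"))
                ep = instance_exit(cur, cur_inst, entry_side)
                supports.append(links[ep[0]].support)
                cur, cur_inst, entry_side = owner[mate[ep]]
                if (cur, cur_inst) == (cid, inst):
                    break
            cycles.append((canonical_order(order), min(supports)))
    return cycles


def _best_pairing(m: dict[str, int], t: dict[int, int], links: list[Link],
                  exact_limit: int, restarts: int, seed: int,
                  lengths: dict[str, int] | None = None,
                  ) -> tuple[list[tuple[Order, int]], str]:
    """Pick junction pairings giving the most subdivided decomposition.

    Among pairings of equal total length, prefer the most circles, then the
    smallest maximal circle (large circles favour subdivision by repeat-
    mediated recombination, so the fully subdivided state is the primary
    presentation), then the lexicographically smallest canonical forms.
    Exhaustive when the product of per-contig pairing counts is within
    ``exact_limit``; otherwise greedy seeded restarts keeping the best.
    """
    slots = _build_slots(m, t, links)
    multi = sorted(cid for cid in slots if m[cid] >= 2)
    n_choices = 1
    for cid in multi:
        n_choices *= math.factorial(m[cid])
    lengths = lengths or {}

    def evaluate(pairing):
        cycles = _trace_cycles(m, t, links, pairing, slots)
        size = tuple(sorted((sum(lengths.get(oc.id, 1) for oc in o)
                             for o, _ in cycles), reverse=True))
        key = (-len(cycles), size, sorted(order_string(o) for o, _ in cycles))
        return key, cycles

    base = {cid: tuple(range(m[cid])) for cid in slots}
    if n_choices <= max(1, exact_limit):
        best_key, best = None, None
        for combo in itertools.product(
                *[list(itertools.permutations(range(m[cid]))) for cid in multi]):
            pairing = dict(base)
            for cid, perm in zip(multi, combo):
                pairing[cid] = perm
            key, cycles = evaluate(pairing)
            if best_key is None or key < best_key:
                best_key, best = key, cycles
        return best, "exact"

    rng = np.random.default_rng(seed)
    best_key, best = evaluate(base)
    for _ in range(restarts):
        pairing = dict(base)
        for cid in multi:
            pairing[cid] = tuple(int(v) for v in rng.permutation(m[cid]))
        key, cycles = evaluate(pairing)
        if key < best_key:
            best_key, best = key, cycles
    return best, "greedy"


def _peel_linear(ids: set[str], links: list[Link],
                 ) -> tuple[set[str], list[list[str]]]:
    """Remove contigs with a linkless end (unclosable into a circle); chain
    the removed contigs into maximal linear-candidate groups."""
    active = set(ids)
    removed: list[str] = []
    changed = True
    while changed:
        changed = False
        live = [l for l in links if l.end_a[0] in active and l.end_b[0] in active]
        for cid in sorted(active):
            if any(not any(l.touches((cid, side)) for l in live)
                   for side in (HEAD, TAIL)):
                active.discard(cid)
                removed.append(cid)
                changed = True
                break
    if not removed:
        return active, []
    G = nx.Graph()
    G.add_nodes_from(removed)
    for l in links:
        if l.end_a[0] in removed and l.end_b[0] in removed:
            G.add_edge(l.end_a[0], l.end_b[0])
    return active, sorted(sorted(c) for c in nx.connected_components(G))


def decompose_circles(g: AssemblyGraph, exact_limit: int = 12,
                      restarts: int = 100, seed: int = 0,
                      ) -> tuple[list[CircularChromosome], list[list[str]], str]:
    """Parsimonious cycle cover of the assembly graph.

    Returns (circles, linear candidate chains, search mode).  Circles from
    the substoichiometric pass carry an ``abundance`` tag (mean depth ratio
    of their flagged contigs).  Raises :class:`StructureError` if the
    full-stoichiometry contigs admit no cover.
    """
    if not g.copy_estimate:
        raise StructureError("copy numbers not estimated; run estimate_copy_numbers")

    sub = set(g.substoichiometric)
    main_ids = set(g.contigs) - sub
    main_links = [l for l in g.links
                  if l.end_a[0] in main_ids and l.end_b[0] in main_ids]
    main_active, linear = _peel_linear(main_ids, main_links)

    cycles: list[tuple[Order, int, float | None]] = []
    mode = "exact"
    if main_active:
        links_main = sorted((l for l in main_links
                             if l.end_a[0] in main_active and l.end_b[0] in main_active),
                            key=lambda l: (l.key, l.support))
        sol = _solve_cover_milp({c: g.contigs[c].length for c in main_active},
                                {c: g.copy_estimate[c] for c in main_active},
                                {c: 1 for c in main_active}, links_main)
        if sol is None:
            raise StructureError(
                f"no cycle cover exists; uncovered contigs: {sorted(main_active)}")
        m, t = sol
        traced, mode = _best_pairing(m, t, links_main, exact_limit, restarts, seed,
                                     {c: g.contigs[c].length for c in main_active})
        cycles.extend((order, sup, None) for order, sup in traced)

    if sub:
        sub_active, sub_linear = _peel_linear(sub | main_active, list(g.links))
        linear.extend(ch for ch in sub_linear if any(c in sub for c in ch))
        present_sub = {c for c in sub if c in sub_active}
        if present_sub:
            links_all = sorted((l for l in g.links
                                if l.end_a[0] in sub_active and l.end_b[0] in sub_active),
                               key=lambda l: (l.key, l.support))
            sol2 = _solve_cover_milp(
                {c: g.contigs[c].length for c in sub_active},
                {c: (g.copy_estimate[c] if c in sub else MAX_BORROW)
                 for c in sub_active},
                {c: (1 if c in sub else 0) for c in sub_active}, links_all)
            if sol2 is None:
                linear.append(sorted(present_sub))
            else:
                m2, t2 = sol2
                m2 = {cid: mm for cid, mm in m2.items() if mm > 0}
                traced2, mode2 = _best_pairing(
                    m2, t2, links_all, exact_limit, restarts, seed,
                    {c: g.contigs[c].length for c in sub_active})
                if mode2 == "greedy":
                    mode = "greedy"
                for order, sup in traced2:
                    flagged = [oc.id for oc in order if oc.id in sub]
                    if not flagged:
                        continue  # pure-backbone artefact cycle
                    ab = float(np.mean([g.depth_ratio[c] for c in flagged]))
                    cycles.append((order, sup, round(ab, 4)))

    def cyc_len(order: Order) -> int:
        return sum(g.contigs[oc.id].length for oc in order)

    cycles.sort(key=lambda c: (-cyc_len(c[0]), order_string(c[0])))
    out = [CircularChromosome(id=f"MC-{i + 1}", order=order, support=sup,
                              length=cyc_len(order), abundance=ab)
           for i, (order, sup, ab) in enumerate(cycles)]
    return out, sorted(linear), mode


# --------------------------------------------------------------------------
# inverted-order alternatives

def _cycle_support(order: Order, support_of: dict[tuple[End, End], int]) -> int:
    n = len(order)
    return sum(support_of.get(junction_ends(order[i], order[(i + 1) % n]), 0)
               for i in range(n))


def enumerate_inverted_orders(circles: list[CircularChromosome],
                              g: AssemblyGraph) -> list[OrderAlternative]:
    """For each circle carrying a repeated contig pair in opposite
    orientations, emit the flipped-block alternative order.

    The primary order is the one whose junctions have the greater summed
    link support (the in-silico surrogate for "more intense PCR
    amplification"); equal support — unavoidable for perfect inverted
    repeats under undirected end-pair evidence — sets the tie flag, broken
    toward the lexicographically smaller canonical order string.
    """
    support_of: dict[tuple[End, End], int] = {}
    for l in g.links:
        support_of[l.key] = support_of.get(l.key, 0) + l.support

    out: list[OrderAlternative] = []
    for circ in circles:
        order = circ.order
        n = len(order)
        pair = None
        for i in range(n):
            for j in range(i + 1, n):
                if (order[i].id == order[j].id
                        and order[i].orientation != order[j].orientation):
                    pair = (i, j)
                    break
            if pair:
                break
        if pair is None:
            continue
        i, j = pair
        arc = order[i + 1:j]
        if arc:
            alt = order[:i + 1] + reverse_order(arc) + order[j:]
        else:
            wrap_arc = order[j + 1:] + order[:i]
            if not wrap_arc:
                continue
            alt = order[i:j + 1] + reverse_order(wrap_arc)
        sup_primary = _cycle_support(order, support_of)
        sup_alt = _cycle_support(alt, support_of)
        tie = sup_primary == sup_alt
        primary, alternative = order, alt
        p_sup, a_sup = sup_primary, sup_alt
        if sup_alt > sup_primary or (tie and order_string(canonical_order(alt))
                                     < order_string(canonical_order(order))):
            primary, alternative = alt, order
            p_sup, a_sup = sup_alt, sup_primary
        out.append(OrderAlternative(
            circle_id=circ.id,
            primary=order_string(canonical_order(primary)),
            alternative=order_string(canonical_order(alternative)),
            primary_support=p_sup, alternative_support=a_sup, tie=tie))
    return out


# --------------------------------------------------------------------------
# subgenome merging

def _insert_circle(acc: Order, circ: Order, repeat_id: str) -> Order:
    """Repeat-mediated insertion of ``circ`` into ``acc`` at the last
    occurrence of ``repeat_id``; every junction (adjacency) of both circles
    survives and the repeat gains one copy per merge.  Splicing into the
    most recently created copy keeps earlier three-contig contexts intact."""
    i = max(k for k, oc in enumerate(acc) if oc.id == repeat_id)
    target = acc[i]
    k = next(k for k, oc in enumerate(circ) if oc.id == repeat_id)
    rot = circ[k:] + circ[:k]
    if rot[0].orientation != target.orientation:
        rot = reverse_order(rot)
        k2 = next(k for k, oc in enumerate(rot)
                  if oc.id == repeat_id and oc.orientation == target.orientation)
        rot = rot[k2:] + rot[:k2]
    return acc[:i + 1] + rot[1:] + (target,) + acc[i + 1:]


def merge_subgenomes(circles: list[CircularChromosome], g: AssemblyGraph,
                     plasmid_max_len: int = 10_000) -> GenomeStructure:
    """Union circles sharing a multi-copy contig into subgenomes and emit the
    merged circular sequence of each.

    Single-contig circles shorter than ``plasmid_max_len`` are set aside as
    plasmid-like molecules (numbered by descending length).  Subgenomes are
    numbered by ascending length.
    """
    plasmid_circles: list[CircularChromosome] = []
    chrom: list[CircularChromosome] = []
    for c in circles:
        if len(c.order) == 1 and c.length < plasmid_max_len:
            plasmid_circles.append(c)
        else:
            chrom.append(c)
    plasmid_circles.sort(key=lambda c: (-c.length, c.id))
    plasmids = [(f"plasmid-{i + 1}", c.sequence(g.contigs))
                for i, c in enumerate(plasmid_circles)]

    multicopy = {cid for cid, k in g.copy_estimate.items() if k >= 2}

    parent = {c.id: c.id for c in chrom}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merge_events: list[tuple[tuple[str, str], str]] = []
    for rid in sorted(multicopy):
        members = sorted((c for c in chrom if rid in c.contig_ids),
                         key=lambda c: c.id)
        for a, b in zip(members, members[1:]):
            if find(a.id) != find(b.id):
                parent[find(b.id)] = find(a.id)
                merge_events.append(((a.id, b.id), rid))

    groups: dict[str, list[CircularChromosome]] = {}
    for c in chrom:
        groups.setdefault(find(c.id), []).append(c)

    built: list[tuple[Order, list[str]]] = []
    for root in sorted(groups):
        members = sorted(groups[root], key=lambda c: (-c.length, c.id))
        acc = members[0].order
        done = [members[0].id]
        pending = members[1:]
        while pending:
            progressed = False
            for c in list(pending):
                acc_ids = {oc.id for oc in acc}
                shared = sorted((c.contig_ids & acc_ids) & multicopy)
                if shared:
                    acc = _insert_circle(acc, c.order, shared[0])
                    done.append(c.id)
                    pending.remove(c)
                    progressed = True
            if not progressed:  # members without multicopy overlap stay separate
                for c in pending:
                    built.append((c.order, [c.id]))
                pending = []
        built.append((canonical_order(acc), sorted(done)))

    def seq_of(order: Order) -> str:
        return "".join(g.contigs[oc.id].seq if oc.orientation == "+"
                       else revcomp(g.contigs[oc.id].seq) for oc in order)

    built.sort(key=lambda b: (sum(g.contigs[oc.id].length for oc in b[0]),
                              ",".join(b[1])))
    subgenomes = [Subgenome(id=f"subgenome-{i + 1}", circle_ids=members,
                            order=order, sequence=seq_of(order))
                  for i, (order, members) in enumerate(built)]

    return GenomeStructure(circles=chrom, plasmids=plasmids,
                           merge_events=merge_events, subgenomes=subgenomes)


# --------------------------------------------------------------------------
# shared repeats between subgenomes

_PACK_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _PACK_ENC[ord(_b)] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Exact 2-bit-packed k-mer codes per position (-1 where the window
    contains a non-ACGT base)."""
    codes = _PACK_ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    bad = codes < 0
    h = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        h = (h << 2) | np.where(bad[j:j + n], 0, codes[j:j + n])
        invalid |= bad[j:j + n]
    h[invalid] = -1
    return h


def _maximal_matches(a: str, b: str, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches (start_a, start_b, length) of length >= min_len
    between ``a`` and ``b``: dense exact k-mer anchors (2-bit packed, k <= 31
    so codes are collision-free) merged along diagonals."""
    k = min(31, min_len)
    ha = _kmer_codes(a, k)
    hb = _kmer_codes(b, k)
    if len(ha) == 0 or len(hb) == 0:
        return []
    order_b = np.argsort(hb, kind="stable")
    hb_sorted = hb[order_b]
    left = np.searchsorted(hb_sorted, ha, side="left")
    right = np.searchsorted(hb_sorted, ha, side="right")
    counts = right - left
    hit_mask = (counts > 0) & (ha >= 0)
    ia_all = np.repeat(np.flatnonzero(hit_mask), counts[hit_mask])
    jb_all = order_b[np.concatenate(
        [np.arange(left[i], right[i]) for i in np.flatnonzero(hit_mask)]
    )] if hit_mask.any() else np.zeros(0, dtype=np.int64)
    if len(ia_all) == 0:
        return []
    diag = ia_all - jb_all
    srt = np.lexsort((ia_all, diag))
    ia_s, diag_s = ia_all[srt], diag[srt]
    breaks = np.flatnonzero((np.diff(diag_s) != 0) | (np.diff(ia_s) != 1))
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(ia_s) - 1]])
    out = []
    for s, e in zip(starts, ends):
        length = int(ia_s[e] - ia_s[s]) + k
        if length >= min_len:
            sa = int(ia_s[s])
            out.append((sa, sa - int(diag_s[s]), length))
    return out


def chained_matches(a: str, b: str, min_len: int, min_identity: float,
                    ) -> list[tuple[int, int, int, float]]:
    """Near-identical local matches (start_a, start_b, length, identity):
    maximal exact runs chained along diagonals across small mismatch gaps
    while the combined identity stays above the floor."""
    raw = _maximal_matches(a, b, min(31, min_len))
    raw.sort(key=lambda r: (r[0] - r[1], r[0]))
    chained: list[list[int]] = []
    for sa, sb, ln in raw:
        if chained:
            pa, pb, pl, mism = chained[-1]
            gap = sa - (pa + pl)
            if sa - sb == pa - pb and gap >= 0:
                tot = sa + ln - pa
                if tot > 0 and 1 - (mism + gap) / tot >= min_identity:
                    chained[-1] = [pa, pb, tot, mism + gap]
                    continue
        chained.append([sa, sb, ln, 0])
    out = []
    for sa, sb, ln, mism in chained:
        ident = 1 - mism / ln
        if ln >= min_len and ident >= min_identity:
            out.append((sa, sb, ln, round(ident, 6)))
    return out


def find_shared_repeats(structure: GenomeStructure, min_len: int = 100,
                        min_identity: float = 0.99) -> list[RepeatMatch]:
    """All maximal matches of length >= min_len and identity >= min_identity
    between the sequences of *different* subgenomes, in both orientations,
    with circular wrap handled by sequence doubling.

    Matches are exact diagonal runs; runs separated by few mismatches are
    chained while the combined identity stays above the floor.
    """
    out: list[RepeatMatch] = []
    subs = structure.subgenomes
    for x in range(len(subs)):
        for y in range(x + 1, len(subs)):
            A, B = subs[x], subs[y]
            la, lb = len(A.sequence), len(B.sequence)
            a2 = A.sequence + A.sequence
            for orientation in ("direct", "inverted"):
                bseq = B.sequence if orientation == "direct" else revcomp(B.sequence)
                b2 = bseq + bseq
                seen = set()
                for sa, sb, ln, ident in chained_matches(a2, b2, min_len,
                                                         min_identity):
                    ln = min(ln, la, lb)
                    if ln < min_len:
                        continue
                    ca = sa % la
                    if orientation == "inverted":
                        cb = (lb - (sb % lb) - ln) % lb
                    else:
                        cb = sb % lb
                    key = (ca, cb, ln)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(RepeatMatch(A.id, ca, B.id, cb, ln, ident, orientation))
    out.sort(key=lambda r: (-r.length, r.molecule_a, r.start_a, r.orientation))
    return out


def propose_master_circles(structure: GenomeStructure,
                           matches: Iterable[RepeatMatch]) -> GenomeStructure:
    """Append one master-circle hypothesis per inter-subgenome repeat match.

    The recombinant is built by a single crossover at the match: each
    subgenome is rotated to start at its repeat copy (the second reverse-
    complemented for an inverted match) and the two are concatenated, so
    both repeat copies persist, one per former junction.
    """
    seq_by_id = {s.id: s.sequence for s in structure.subgenomes}
    for mt in matches:
        if mt.molecule_a not in seq_by_id or mt.molecule_b not in seq_by_id:
            continue
        A = seq_by_id[mt.molecule_a]
        B = seq_by_id[mt.molecule_b]
        arot = A[mt.start_a:] + A[:mt.start_a]
        if mt.orientation == "inverted":
            B = revcomp(B)
            sb = len(B) - mt.start_b - mt.length
        else:
            sb = mt.start_b
        brot = B[sb:] + B[:sb]
        structure.master_hypotheses.append(MasterCircleHypothesis(
            subgenome_a=mt.molecule_a, subgenome_b=mt.molecule_b, match=mt,
            length=len(A) + len(B), sequence=arot + brot))
    return structure


def compute_gc(structure: GenomeStructure, contigs=None) -> dict[str, float]:
    """GC percentage (reported to 0.1%) per subgenome and plasmid-like
    molecule, plus per chromosome circle when contig sequences are given.
    N bases are excluded; a zero-length molecule is an input error."""
    out: dict[str, float] = {}
    for s in structure.subgenomes:
        if len(s.sequence) == 0:
            raise ValueError(f"zero-length molecule {s.id}")
        out[s.id] = round(100 * gc_fraction(s.sequence), 1)
    for pid, seq in structure.plasmids:
        if len(seq) == 0:
            raise ValueError(f"zero-length molecule {pid}")
        out[pid] = round(100 * gc_fraction(seq), 1)
    if contigs is not None:
        for c in structure.circles:
            out[c.id] = round(100 * gc_fraction(c.sequence(contigs)), 1)
    return out
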
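"""Assembly graph: contigs, end-to-end link evidence, and depth-based
copy-number estimation.

A contig has two ends, head (``H``, the 5' end of the stored strand) and tail
(``T``).  A link joins two contig ends and abstracts paired-end bridge
evidence: traversing a contig head-to-tail reads its stored strand ('+'),
tail-to-head its reverse complement ('−').

Copy numbers are estimated from mean read depth against a single-copy
baseline.  The baseline is the median depth of the dominant mode — contigs
whose depth lies within ±35% of the overall median — which is robust to a
minority of repeats (high depth) and substoichiometric molecules (low depth).
Contigs below half the baseline are flagged substoichiometric and keep copy
estimate 1; they represent minor genome configurations, not extra copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from ._seq import gc_fraction

HEAD = "H"
TAIL = "T"


class InputError(ValueError):
    """Inconsistent inputs (unknown contig, duplicate id, ...)."""


class EstimationError(ValueError):
    """Copy-number estimation cannot proceed (e.g. all depths zero)."""


@dataclass
class Contig:
    """A sequenced DNA segment, the atom of the assembly graph."""
    id: str
    seq: str
    mean_depth: float = 0.0

    def __post_init__(self):
        if len(self.seq) == 0:
            raise InputError(f"contig {self.id!r}: empty sequence")
        if self.mean_depth < 0:
            raise InputError(f"contig {self.id!r}: negative depth")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)


End = tuple[str, str]  # (contig id, HEAD|TAIL)


@dataclass(frozen=True)
class Link:
    """Bridge evidence joining two contig ends (undirected; self-links allowed)."""
    end_a: End
    end_b: End
    support: int = 1

    def __post_init__(self):
        if self.support < 1:
            raise InputError("link support must be >= 1")
        for end in (self.end_a, self.end_b):
            if end[1] not in (HEAD, TAIL):
                raise InputError(f"link end side must be H or T, got {end[1]!r}")

    @property
    def key(self) -> tuple[End, End]:
        """Canonical unordered end pair."""
        return tuple(sorted([self.end_a, self.end_b]))  # type: ignore[return-value]

    def touches(self, end: End) -> int:
        """How many of this link's endpoints sit on ``end`` (0, 1 or 2)."""
        return (self.end_a == end) + (self.end_b == end)


@dataclass
class AssemblyGraph:
    contigs: dict[str, Contig]
    links: list[Link]
    single_copy_depth: float | None = None
    copy_estimate: dict[str, int] = field(default_factory=dict)
    depth_ratio: dict[str, float] = field(default_factory=dict)
    substoichiometric: set[str] = field(default_factory=set)

    def links_at(self, end: End) -> list[Link]:
        return [l for l in self.links if l.touches(end)]

    def component_sets(self) -> list[set[str]]:
        """Connected components over contigs (self-links do not connect)."""
        G = nx.Graph()
        G.add_nodes_from(self.contigs)
        for l in self.links:
            G.add_edge(l.end_a[0], l.end_b[0])
        return [set(c) for c in nx.connected_components(G)]

    @property
    def isolated(self) -> list[str]:
        """Contigs with no link touching either end (candidate plasmid-like
        molecules when a circularising self-link is absent)."""
        linked = {e[0] for l in self.links for e in (l.end_a, l.end_b)}
        return sorted(c for c in self.contigs if c not in linked)


def build_graph(contigs: list[Contig] | dict[str, Contig],
                links: list[Link] | pd.DataFrame,
                depth_summary: pd.DataFrame | dict[str, float] | None = None,
                ) -> AssemblyGraph:
    """Assemble parsed inputs into an :class:`AssemblyGraph`.

    ``links`` may be a dataframe in the links.tsv schema.  ``depth_summary``
    (contig → mean depth) overrides any depths already on the contigs.
    """
    if not isinstance(contigs, dict):
        cmap: dict[str, Contig] = {}
        for c in contigs:
            if c.id in cmap:
                raise InputError(f"duplicate contig id {c.id!r}")
            cmap[c.id] = c
        contigs = cmap

    if isinstance(links, pd.DataFrame):
        parsed = []
        for row in links.itertuples(index=True):
            parsed.append(Link((row.contig_a, row.end_a), (row.contig_b, row.end_b),
                               int(row.support)))
        link_list = parsed
    else:
        link_list = list(links)

    for i, l in enumerate(link_list):
        for end in (l.end_a, l.end_b):
            if end[0] not in contigs:
                raise InputError(f"link row {i}: unknown contig {end[0]!r}")

    if depth_summary is not None:
        if isinstance(depth_summary, pd.DataFrame):
            depth_map = dict(zip(depth_summary["contig"], depth_summary["mean_depth"]))
        else:
            depth_map = dict(depth_summary)
        for cid, d in depth_map.items():
            if cid not in contigs:
                raise InputError(f"depth row for unknown contig {cid!r}")
            contigs[cid].mean_depth = float(d)

    return AssemblyGraph(contigs=contigs, links=link_list)


def estimate_copy_numbers(g: AssemblyGraph,
                          mode_window: float = 0.35,
                          sub_threshold: float = 0.5) -> AssemblyGraph:
    """Estimate per-contig copy numbers from mean depths (in place).

    baseline = median depth of contigs within ``±mode_window`` of the overall
    median; ``copy_estimate(c) = max(1, round(depth_c / baseline))``.  Contigs
    with ratio below ``sub_threshold`` keep estimate 1 and are flagged
    substoichiometric.
    """
    depths = pd.Series({c.id: c.mean_depth for c in g.contigs.values()})
    if len(depths) < 3:
        raise EstimationError("need at least 3 contigs with depth")
    if (depths <= 0).all():
        raise EstimationError("all contig depths are zero")

    overall = depths.median()
    dominant = depths[(depths >= overall * (1 - mode_window))
                      & (depths <= overall * (1 + mode_window))]
    if dominant.empty:
        dominant = depths
    baseline = float(dominant.median())

    g.single_copy_depth = baseline
    g.copy_estimate = {}
    g.depth_ratio = {}
    g.substoichiometric = set()
    for cid, d in depths.items():
        ratio = d / baseline
        g.depth_ratio[cid] = ratio
        if ratio < sub_threshold:
            g.copy_estimate[cid] = 1
            g.substoichiometric.add(cid)
        else:
            g.copy_estimate[cid] = max(1, math.floor(ratio + 0.5))
    return g
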
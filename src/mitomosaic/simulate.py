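"""Synthetic multipartite mitochondrial genomes and their observation as
assembly inputs.

The generator realises a configured set of circular chromosomes (which may
share repeat segments, within and across circles), plasmid-like molecules,
planted ORFs (optionally chimeric, with a declared fraction donated by a
named gene, and optionally carrying a hydrophobic transmembrane stretch) and
known genes, then "sequences" the genome the way a shotgun assembly sees it:
one contig per distinct segment (repeats collapse), per-base Poisson read
depth proportional to the summed copy number of the molecules carrying each
segment, and end-to-end link support proportional to junction copy number.

All randomness flows from ``SimConfig.seed``; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import (CASSETTE_PAD, STOP_CODONS, STOP_SHIELD_CODONS, random_dna,
                   random_orf_codons, revcomp, scrub_motif)
from .graph import AssemblyGraph, Contig, Link
from .io import Feature, write_fasta, write_links_tsv
from .resolve import (CircularChromosome, GenomeStructure, OrientedContig,
                      canonical_order, junction_ends, merge_subgenomes)

# codons for strongly hydrophobic residues (I, L, V, F), used for planted
# transmembrane stretches
_HYDRO_CODONS = ["ATT", "ATC", "CTT", "CTG", "GTT", "GTC", "TTT", "TTC"]

_CODON_TABLE = {}


def _codon_table():
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
    return _CODON_TABLE


class ConfigError(ValueError):
    """An invalid simulation configuration."""


@dataclass
class CircleSpec:
    """A circular chromosome as an ordered, oriented segment walk."""
    id: str
    segments: tuple[tuple[str, str], ...]  # (segment id, '+'|'-')
    copy_number: float = 1.0
    isomer_fraction: float = 0.0  # link share of the flipped inverted-repeat form


@dataclass
class PlasmidSpec:
    id: str
    length: int
    gc: float | None = None
    copy_number: float = 1.0


@dataclass
class SharedBlock:
    """An identical sequence block written at several segment positions
    (the inter-subgenome recombination substrate)."""
    name: str
    length: int
    placements: tuple[tuple[str, int], ...]  # (segment, offset)


@dataclass
class GeneSpec:
    """A known gene: one or more exons at fixed segment positions.

    Coding genes are single-exon, generated as ATG + sense codons + stop so
    that donated chimera fragments stay in frame and stop-free.  ``copy_to``
    plants additional identical copies (duplicated loci)."""
    name: str
    exons: tuple[tuple[str, int, int], ...]  # (segment, offset, length)
    coding: bool = True
    copy_to: tuple[tuple[str, int], ...] = ()


@dataclass
class PlantedOrf:
    """An ORF written into a host segment.

    The cassette is ``PAD + TAA + ATG + sense codons + TAA + PAD``: the pads
    stop every reading frame on both strands at the cassette boundary (so no
    outside frame reads through), and the in-frame ``TAA`` pins the called
    ORF to the planted ATG.  Within the cassette, stop-shield codon runs
    confine out-of-frame ORFs below the calling floor without touching the
    encoded peptide frame.  ``chimera = (donor gene, fraction)`` replaces
    that fraction of the codons with an in-frame fragment of the donor's
    coding sequence.
    """
    name: str
    peptide_length: int
    host_segment: str
    offset: int
    strand: str = "+"
    chimera: tuple[str, float] | None = None
    in_reference: bool = False
    tm_segment: bool = False

    @property
    def orf_nt(self) -> int:
        return 3 * (self.peptide_length + 1)

    @property
    def cassette_nt(self) -> int:
        return self.orf_nt + 3 + 2 * len(CASSETTE_PAD)


@dataclass
class SimConfig:
    seed: int
    segments: dict[str, int]
    circles: list[CircleSpec]
    plasmids: list[PlasmidSpec] = field(default_factory=list)
    coverage: float = 50.0
    gc_target: float = 0.44
    shared_blocks: list[SharedBlock] = field(default_factory=list)
    motif_plants: list[tuple[str, int, str]] = field(default_factory=list)
    motif_free_windows: list[tuple[str, int, int, str]] = field(default_factory=list)
    base_edits: list[tuple[str, int, str]] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)
    planted_orfs: list[PlantedOrf] = field(default_factory=list)
    bridge_rate: float = 0.25
    noise_model: str = "poisson"

    def validate(self) -> None:
        if not 0 < self.gc_target < 1:
            raise ConfigError("gc_target must be in (0, 1)")
        if self.noise_model != "poisson":
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        for sid, length in self.segments.items():
            if length <= 0:
                raise ConfigError(f"segment {sid!r}: non-positive length")
        for circ in self.circles:
            if circ.copy_number <= 0:
                raise ConfigError(f"circle {circ.id!r}: copy number must be > 0")
            for sid, orient in circ.segments:
                if sid not in self.segments:
                    raise ConfigError(
                        f"circle {circ.id!r} references unknown segment {sid!r}")
                if orient not in "+-":
                    raise ConfigError(f"bad orientation {orient!r}")
        for p in self.plasmids:
            if p.length <= 0 or p.copy_number <= 0:
                raise ConfigError(f"plasmid {p.id!r}: invalid length/copy number")
        gene_names = [g.name for g in self.genes]
        if len(set(gene_names)) != len(gene_names):
            raise ConfigError("duplicate gene names")
        seg_len = dict(self.segments)
        for p in self.plasmids:
            seg_len[p.id] = p.length
        for orf in self.planted_orfs:
            if orf.peptide_length < 1:
                raise ConfigError(f"{orf.name}: peptide_length must be >= 1")
            host_len = seg_len.get(orf.host_segment)
            if host_len is None:
                raise ConfigError(f"{orf.name}: unknown host segment")
            if orf.offset < 0 or orf.offset + orf.cassette_nt > host_len:
                raise ConfigError(
                    f"{orf.name}: planted ORF does not fit host molecule")
            if orf.chimera is not None:
                donor, frac = orf.chimera
                if not 0 < frac < 1:
                    raise ConfigError(f"{orf.name}: chimera fraction must be in (0,1)")
                if donor not in gene_names:
                    raise ConfigError(f"{orf.name}: unknown chimera donor {donor!r}")
        # non-overlapping planted intervals per segment
        registry: dict[str, list[tuple[int, int, str]]] = {}

        def claim(seg, start, end, what):
            for s, e, other in registry.get(seg, []):
                if start < e and s < end:
                    raise ConfigError(
                        f"planted features overlap on {seg}: {what} vs {other}")
            registry.setdefault(seg, []).append((start, end, what))

        for b in self.shared_blocks:
            for seg, off in b.placements:
                claim(seg, off, off + b.length, f"block {b.name}")
        for g in self.genes:
            for seg, off, ln in g.exons:
                claim(seg, off, off + ln, f"gene {g.name}")
            for seg, off in g.copy_to:
                total = sum(ln for _, _, ln in g.exons)
                claim(seg, off, off + total, f"gene {g.name} copy")
        for orf in self.planted_orfs:
            claim(orf.host_segment, orf.offset, orf.offset + orf.cassette_nt,
                  f"orf {orf.name}")
        for seg, off, motif in self.motif_plants:
            claim(seg, off, off + len(motif), f"motif@{seg}:{off}")


@dataclass
class RealizedOrf:
    name: str
    molecule: str
    start: int  # 0-based, ORF span incl. stop codon, molecule coordinates
    end: int
    strand: str
    peptide_length: int
    seq: str  # ATG ... stop, reading-frame orientation
    host_segment: str
    chimera: tuple[str, float] | None
    in_reference: bool
    tm_segment: bool


@dataclass
class RealizedGene:
    name: str
    coding: bool
    seq: str  # concatenated exon sequence (reading orientation)
    parts: list[tuple[str, int, int, str, int]]  # (molecule, start, end, strand, exon)


@dataclass
class TruthSet:
    config: SimConfig
    segment_sequences: dict[str, str]
    molecule_sequences: dict[str, str]
    genome: GenomeStructure
    planted: list[RealizedOrf]
    genes: list[RealizedGene]
    block_positions: dict[str, list[tuple[str, int]]]  # block -> (molecule, start)


@dataclass
class DepthProfile:
    per_base: dict[str, np.ndarray]
    summary: pd.DataFrame  # contig, mean_depth


# --------------------------------------------------------------------------

def _segment_occurrences(cfg: SimConfig) -> dict[str, list[tuple[str, int, str]]]:
    """segment id -> [(molecule, position in molecule, orientation)]"""
    occ: dict[str, list[tuple[str, int, str]]] = {}
    for circ in cfg.circles:
        pos = 0
        for sid, orient in circ.segments:
            occ.setdefault(sid, []).append((circ.id, pos, orient))
            pos += cfg.segments[sid]
    for p in cfg.plasmids:
        occ.setdefault(p.id, []).append((p.id, 0, "+"))
    return occ


def _all_molecule_coords(cfg: SimConfig, occ, seg: str, start: int, end: int,
                         strand: str) -> list[tuple[str, int, int, str]]:
    """Map a segment-local interval to molecule coordinates, one entry per
    occurrence of the segment."""
    seg_len = cfg.segments.get(seg)
    if seg_len is None:
        seg_len = next(p.length for p in cfg.plasmids if p.id == seg)
    out = []
    for mol, base, orient in occ.get(seg, []):
        if orient == "+":
            out.append((mol, base + start, base + end, strand))
        else:
            flipped = "-" if strand == "+" else "+"
            out.append((mol, base + seg_len - end, base + seg_len - start, flipped))
    return out


def _molecule_coords(cfg: SimConfig, occ, seg: str, start: int, end: int,
                     strand: str) -> tuple[str, int, int, str]:
    """Map a segment-local interval to unique molecule coordinates."""
    places = _all_molecule_coords(cfg, occ, seg, start, end, strand)
    if len(places) != 1:
        raise ConfigError(
            f"planted feature host {seg!r} occurs {len(places)} times; "
            "features must live on single-occurrence segments")
    return places[0]


def simulate_genome(cfg: SimConfig) -> TruthSet:
    """Realise the configured genome; reproducible given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    seg_gc = {sid: cfg.gc_target for sid in cfg.segments}
    seg_len = dict(cfg.segments)
    for p in cfg.plasmids:
        seg_len[p.id] = p.length
        seg_gc[p.id] = p.gc if p.gc is not None else cfg.gc_target

    seqs: dict[str, list[str]] = {}
    for sid in sorted(seg_len):
        seqs[sid] = list(random_dna(rng, seg_len[sid], seg_gc[sid]))

    def write(seg: str, off: int, s: str):
        seqs[seg][off:off + len(s)] = list(s)

    # motif-free windows (keep engineered restriction maps exact)
    for seg, start, end, motif in cfg.motif_free_windows:
        window = "".join(seqs[seg][start:end])
        write(seg, start, scrub_motif(window, motif))

    # shared identical blocks
    blocks: dict[str, str] = {}
    for b in cfg.shared_blocks:
        block = random_dna(rng, b.length, cfg.gc_target)
        for _, _, _, motif in cfg.motif_free_windows:
            block = scrub_motif(block, motif)
        blocks[b.name] = block
        for seg, off in b.placements:
            write(seg, off, block)

    for seg, pos, base in cfg.base_edits:
        seqs[seg][pos] = base

    for seg, off, motif in cfg.motif_plants:
        write(seg, off, motif)

    # known genes
    genes_seq: dict[str, str] = {}
    for g in sorted(cfg.genes, key=lambda g: g.name):
        total = sum(ln for _, _, ln in g.exons)
        if g.coding:
            if total % 3 or total < 9:
                raise ConfigError(f"gene {g.name}: coding length must be 3n >= 9")
            n_codons = total // 3 - 2
            bulk = random_orf_codons(rng, n_codons, cfg.gc_target)
            codons = [bulk[i:i + 3] for i in range(0, len(bulk), 3)]
            _place_shields(codons, [])
            seq = "ATG" + "".join(codons) + "TAA"
        else:
            seq = random_dna(rng, total, cfg.gc_target)
        genes_seq[g.name] = seq
        pos = 0
        for seg, off, ln in g.exons:
            write(seg, off, seq[pos:pos + ln])
            pos += ln
        for seg, off in g.copy_to:
            write(seg, off, seq)

    # planted ORFs
    orf_seqs: dict[str, str] = {}
    for orf in cfg.planted_orfs:
        pl = orf.peptide_length
        bulk = random_orf_codons(rng, pl - 1, cfg.gc_target)
        codons = [bulk[i:i + 3] for i in range(0, len(bulk), 3)]
        obstacles: list[tuple[int, int]] = []
        anchored: list[tuple[int, int]] = []
        if orf.chimera is not None:
            donor, frac = orf.chimera
            dseq = genes_seq[donor]
            donor_codons = [dseq[i:i + 3] for i in range(3, len(dseq) - 3, 3)]
            k = max(10, round(frac * pl))
            if len(donor_codons) < 7 + k:
                raise ConfigError(f"{orf.name}: donor {donor} too short for fragment")
            if 5 + k + len(STOP_SHIELD_CODONS) > pl - 1:
                raise ConfigError(f"{orf.name}: chimera fragment exceeds ORF")
            codons[5:5 + k] = donor_codons[7:7 + k]
            obstacles.append((5, 5 + k))
            anchored.append((5, 5 + k))  # donor interiors carry gene shields
            p = 5 + k
            codons[p:p + len(STOP_SHIELD_CODONS)] = list(STOP_SHIELD_CODONS)
            obstacles.append((p, p + len(STOP_SHIELD_CODONS)))
            anchored.append((p, p + len(STOP_SHIELD_CODONS)))
        if orf.tm_segment:
            lo, hi = pl - 31, pl - 6
            if lo < len(STOP_SHIELD_CODONS):
                raise ConfigError(f"{orf.name}: too short for a TM stretch")
            if obstacles and obstacles[-1][1] > lo - len(STOP_SHIELD_CODONS):
                raise ConfigError(f"{orf.name}: chimera and TM stretches overlap")
            for i in range(lo, hi):
                codons[i] = _HYDRO_CODONS[rng.integers(len(_HYDRO_CODONS))]
            obstacles.append((lo, hi))
            p = lo - len(STOP_SHIELD_CODONS)
            codons[p:p + len(STOP_SHIELD_CODONS)] = list(STOP_SHIELD_CODONS)
            obstacles.append((p, lo))
            anchored.append((p, lo))
        _place_shields(codons, obstacles, anchored)
        orf_seq = "ATG" + "".join(codons) + "TAA"
        orf_seqs[orf.name] = orf_seq
        cassette = CASSETTE_PAD + "TAA" + orf_seq + CASSETTE_PAD
        _check_foreign_frames(cassette, orf.name)
        if orf.strand == "-":
            cassette = revcomp(cassette)
        write(orf.host_segment, orf.offset, cassette)

    segment_sequences = {sid: "".join(s) for sid, s in seqs.items()}

    # assemble molecules
    molecule_sequences: dict[str, str] = {}
    for circ in cfg.circles:
        molecule_sequences[circ.id] = "".join(
            segment_sequences[sid] if orient == "+" else revcomp(segment_sequences[sid])
            for sid, orient in circ.segments)
    for p in cfg.plasmids:
        molecule_sequences[p.id] = segment_sequences[p.id]

    occ = _segment_occurrences(cfg)

    # realized coordinates
    planted: list[RealizedOrf] = []
    pad = len(CASSETTE_PAD)
    for orf in cfg.planted_orfs:
        if orf.strand == "+":
            s = orf.offset + pad + 3
        else:
            s = orf.offset + pad
        e = s + orf.orf_nt
        mol, ms, me, strand = _molecule_coords(cfg, occ, orf.host_segment, s, e,
                                               orf.strand)
        oseq = orf_seqs[orf.name]
        planted.append(RealizedOrf(orf.name, mol, ms, me, strand,
                                   orf.peptide_length, oseq, orf.host_segment,
                                   orf.chimera, orf.in_reference, orf.tm_segment))
        _check_orf(oseq, orf.peptide_length, orf.name)

    genes: list[RealizedGene] = []
    for g in sorted(cfg.genes, key=lambda g: g.name):
        parts = []
        for n, (seg, off, ln) in enumerate(g.exons, 1):
            for mol, ms, me, strand in _all_molecule_coords(
                    cfg, occ, seg, off, off + ln, "+"):
                parts.append((mol, ms, me, strand, n))
        for seg, off in g.copy_to:
            total = len(genes_seq[g.name])
            for mol, ms, me, strand in _all_molecule_coords(
                    cfg, occ, seg, off, off + total, "+"):
                parts.append((mol, ms, me, strand, 1))
        genes.append(RealizedGene(g.name, g.coding, genes_seq[g.name], parts))

    block_positions: dict[str, list[tuple[str, int]]] = {}
    for b in cfg.shared_blocks:
        placed = []
        for seg, off in b.placements:
            mol, ms, _me, _ = _molecule_coords(cfg, occ, seg, off, off + b.length, "+")
            placed.append((mol, ms))
        block_positions[b.name] = placed

    genome = _truth_structure(cfg, segment_sequences)

    return TruthSet(config=cfg, segment_sequences=segment_sequences,
                    molecule_sequences=molecule_sequences, genome=genome,
                    planted=planted, genes=genes, block_positions=block_positions)


def _place_shields(codons: list[str], obstacles=(), anchored=(),
                   max_gap: int = 50) -> None:
    """Insert stop-shield runs so that no stretch between stop-bearing
    anchors exceeds ``max_gap`` codons, keeping out-of-frame open reading
    frames below the calling floor.  ``obstacles`` are codon intervals that
    must not be overwritten; ``anchored`` intervals already confine foreign
    frames (donor fragments with their own internal shields, placed
    shields)."""
    n = len(codons)
    S = len(STOP_SHIELD_CODONS)
    obstacles = sorted(obstacles)

    def blocked(p: int) -> bool:
        return any(p < e and s < p + S for s, e in obstacles)

    anchors = sorted([(-1, 0)] + list(anchored) + [(n, n + 1)])
    for (_, e0), (s1, _) in zip(anchors, anchors[1:]):
        pos = e0
        while s1 - pos > max_gap:
            p = pos + max_gap - S
            while p > pos and blocked(p):
                p -= 1
            if p <= pos or p + S > s1:
                break
            codons[p:p + S] = list(STOP_SHIELD_CODONS)
            pos = p + S


def _check_foreign_frames(cassette: str, name: str, limit: int = 66) -> None:
    """Defence in depth: no foreign reading frame (either strand, excluding
    the encoded one) may run stop-free for ``limit`` codons within the
    cassette."""
    for plus, strand_seq in ((True, cassette), (False, revcomp(cassette))):
        for f in range(3):
            if plus and f == 0:
                continue  # the encoded frame legitimately runs the ORF length
            run = 0
            for i in range(f, len(strand_seq) - 2, 3):
                if strand_seq[i:i + 3] in STOP_CODONS:
                    run = 0
                else:
                    run += 1
                    if run >= limit:
                        raise ConfigError(
                            f"{name}: foreign-frame run >= {limit} codons")


def _check_orf(seq: str, peptide_length: int, name: str) -> None:
    if len(seq) != 3 * (peptide_length + 1) or not seq.startswith("ATG"):
        raise ConfigError(f"{name}: malformed planted ORF")
    table = _codon_table()
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in STOP_CODONS:
            raise ConfigError(f"{name}: internal stop in planted ORF")
        assert seq[i:i + 3] in table
    if seq[-3:] not in STOP_CODONS:
        raise ConfigError(f"{name}: planted ORF lacks terminal stop")


def _truth_structure(cfg: SimConfig, segment_sequences) -> GenomeStructure:
    """The configured genome as a GenomeStructure (truth labels)."""
    weighted: dict[str, float] = {}
    for circ in cfg.circles:
        for sid, _ in circ.segments:
            weighted[sid] = weighted.get(sid, 0.0) + circ.copy_number
    for p in cfg.plasmids:
        weighted[p.id] = weighted.get(p.id, 0.0) + p.copy_number

    contigs = {sid: Contig(sid, seq) for sid, seq in segment_sequences.items()}
    shim = AssemblyGraph(contigs=contigs, links=[])
    shim.copy_estimate = {sid: max(1, int(np.floor(w + 0.5)))
                          for sid, w in weighted.items()}

    circles = []
    for circ in cfg.circles:
        order = canonical_order([OrientedContig(s, o) for s, o in circ.segments])
        circles.append(CircularChromosome(
            id=circ.id, order=order, support=0,
            length=sum(cfg.segments[s] for s, _ in circ.segments),
            abundance=None if circ.copy_number >= 0.5 else circ.copy_number))
    for p in cfg.plasmids:
        circles.append(CircularChromosome(
            id=p.id, order=(OrientedContig(p.id, "+"),), support=0, length=p.length))
    return merge_subgenomes(circles, shim)


# --------------------------------------------------------------------------
# observation

def _flipped_order(order: tuple[tuple[str, str], ...]):
    """Flip the arc between the first inverted repeat pair (isomerisation)."""
    n = len(order)
    for i in range(n):
        for j in range(i + 1, n):
            if order[i][0] == order[j][0] and order[i][1] != order[j][1]:
                arc = order[i + 1:j]
                if arc:
                    flipped = tuple((s, "-" if o == "+" else "+")
                                    for s, o in reversed(arc))
                    return order[:i + 1] + flipped + order[j:]
                wrap = order[j + 1:] + order[:i]
                if wrap:
                    flipped = tuple((s, "-" if o == "+" else "+")
                                    for s, o in reversed(wrap))
                    return order[i:j + 1] + flipped
    return None


def fragment_and_observe(truth: TruthSet, cfg: SimConfig | None = None,
                         ) -> tuple[list[Contig], list[Link], DepthProfile]:
    """Observe the genome as an assembler would: collapsed contigs, Poisson
    per-base depths and Poisson link support.  Truth labels are stripped.

    Depth mean per base is ``coverage × Σ copy numbers of molecules carrying
    the segment``; link support mean is ``bridge_rate × coverage × junction
    copy sum`` (junctions of a circle's flipped inverted-repeat isomer
    receive the configured ``isomer_fraction`` share).  Zero-support draws
    emit no link row.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)

    copysum: dict[str, float] = {}
    for circ in cfg.circles:
        for sid, _ in circ.segments:
            copysum[sid] = copysum.get(sid, 0.0) + circ.copy_number
    for p in cfg.plasmids:
        copysum[p.id] = copysum.get(p.id, 0.0) + p.copy_number

    contigs: list[Contig] = []
    per_base: dict[str, np.ndarray] = {}
    for sid in sorted(copysum):
        seq = truth.segment_sequences[sid]
        depths = rng.poisson(cfg.coverage * copysum[sid], size=len(seq))
        per_base[sid] = depths
        contigs.append(Contig(sid, seq, float(depths.mean())))

    junction_mean: dict[tuple, float] = {}

    def add_adjacencies(order, weight):
        n = len(order)
        for i in range(n):
            a = OrientedContig(*order[i])
            b = OrientedContig(*order[(i + 1) % n])
            key = junction_ends(a, b)
            junction_mean[key] = junction_mean.get(key, 0.0) + weight

    for circ in cfg.circles:
        f = circ.isomer_fraction
        add_adjacencies(circ.segments, (1 - f) * circ.copy_number)
        if f > 0:
            flipped = _flipped_order(circ.segments)
            if flipped is not None:
                add_adjacencies(flipped, f * circ.copy_number)
            else:
                add_adjacencies(circ.segments, f * circ.copy_number)
    for p in cfg.plasmids:
        add_adjacencies(((p.id, "+"),), p.copy_number)

    links: list[Link] = []
    for key in sorted(junction_mean):
        support = int(rng.poisson(cfg.bridge_rate * cfg.coverage
                                  * junction_mean[key]))
        if support > 0:
            links.append(Link(key[0], key[1], support))

    summary = pd.DataFrame({
        "contig": [c.id for c in contigs],
        "mean_depth": [round(c.mean_depth, 4) for c in contigs],
    })
    return contigs, links, DepthProfile(per_base=per_base, summary=summary)


# --------------------------------------------------------------------------
# matched reference

REFERENCE_PAD = 3000  # circular-junction pad appended to each record


def make_reference(truth: TruthSet, cfg: SimConfig | None = None,
                   pad: int = REFERENCE_PAD,
                   ) -> tuple[dict[str, str], list[Feature], dict[str, int]]:
    """A matched reference mitogenome: every truth molecule copied, with the
    ``in_reference=False`` planted ORFs overwritten by fresh random sequence,
    and gene annotations for the known genes (chimera donors included).

    Records carry a circular-junction pad (the first ``pad`` bases repeated
    after the end) so origin-spanning ORFs remain alignable; annotation
    coordinates stay within the unpadded length, which is also returned.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 2)

    ref: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for mol in sorted(truth.molecule_sequences):
        seq = list(truth.molecule_sequences[mol])
        for orf in truth.planted:
            if orf.molecule == mol and not orf.in_reference:
                seq[orf.start:orf.end] = list(
                    random_dna(rng, orf.end - orf.start, cfg.gc_target))
        full = "".join(seq)
        lengths[f"NB_{mol}"] = len(full)
        ref[f"NB_{mol}"] = full + full[:min(pad, len(full))]

    features: list[Feature] = []
    for gene in truth.genes:
        for (mol, s, e, strand, exon) in gene.parts:
            ftype = "CDS" if gene.coding and len(gene.parts) == 1 else "exon"
            if gene.coding and any(p[4] == 1 for p in gene.parts[1:]):
                ftype = "CDS"  # duplicated single-exon locus
            features.append(Feature(
                seqid=f"NB_{mol}", type=ftype, start=s, end=e, strand=strand,
                id=f"{gene.name}.{mol}.{exon}.{s}",
                attributes={"gene": gene.name, "exon_number": str(exon)}))
    return ref, features, lengths


# --------------------------------------------------------------------------
# on-disk observation bundle (the CLI surface of the simulator)

def write_observations(outdir: str | Path, truth: TruthSet,
                       contigs: list[Contig], links: list[Link],
                       depths: DepthProfile, per_base: bool = False) -> None:
    """Write contigs.fasta, links.tsv, depth_summary.tsv (and depths.tsv on
    request), reference.fasta + reference.gff3, and truth.json (tests only)."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "contigs.fasta", {c.id: c.seq for c in contigs})
    write_links_tsv(outdir / "links.tsv", pd.DataFrame(
        [{"contig_a": l.end_a[0], "end_a": l.end_a[1],
          "contig_b": l.end_b[0], "end_b": l.end_b[1], "support": l.support}
         for l in links]))
    depths.summary.to_csv(outdir / "depth_summary.tsv", sep="\t", index=False)
    if per_base:
        rows = []
        for cid in sorted(depths.per_base):
            arr = depths.per_base[cid]
            rows.append(pd.DataFrame({"contig": cid,
                                      "position": np.arange(len(arr)),
                                      "depth": arr}))
        pd.concat(rows).to_csv(outdir / "depths.tsv", sep="\t", index=False)

    ref, feats, lengths = make_reference(truth)
    write_fasta(outdir / "reference.fasta", ref)
    from .io import write_gff3
    write_gff3(outdir / "reference.gff3", feats, lengths)

    truth_json = {
        "molecules": {k: len(v) for k, v in truth.molecule_sequences.items()},
        "circles": [{"id": c.id, "order": [str(oc) for oc in c.order],
                     "length": c.length, "abundance": c.abundance}
                    for c in truth.genome.circles],
        "planted_orfs": [{
            "name": o.name, "molecule": o.molecule, "start": o.start,
            "end": o.end, "strand": o.strand, "peptide_length": o.peptide_length,
            "chimera": list(o.chimera) if o.chimera else None,
            "in_reference": o.in_reference, "tm_segment": o.tm_segment,
        } for o in truth.planted],
        "blocks": truth.block_positions,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
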
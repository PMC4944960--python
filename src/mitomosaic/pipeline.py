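"""End-to-end orchestration: simulate (or load) → graph → structure →
stoichiometry → ORF screen → in-silico validation, with one machine-readable
summary.

A single seed governs every stochastic stage (the stages draw from
deterministically split streams), so rerunning with the same configuration
and seed reproduces every artifact byte for byte.  All thresholds live in
:class:`Thresholds` with the study's values as defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .graph import AssemblyGraph, build_graph, estimate_copy_numbers
from .io import Feature, write_fasta, write_gff3, write_json
from .orfs import (OrfRecord, annotate_known_genes, annotate_tm, assign_names,
                   classify_vs_reference, detect_chimeras, find_orfs,
                   gene_sequences, scan_orfs)
from .resolve import (GenomeStructure, compute_gc, decompose_circles,
                      enumerate_inverted_orders, find_shared_repeats,
                      merge_subgenomes, propose_master_circles)
from .simulate import (DepthProfile, SimConfig, TruthSet, fragment_and_observe,
                       make_reference, simulate_genome)
from .stoichiometry import AbundanceEstimate, estimate_abundance
from .validate import Amplicon, DigestFragment, PrimerPair, virtual_digest, virtual_pcr


@dataclass
class Thresholds:
    min_aa: int = 70                 # ORF peptide floor
    identity_floor: float = 0.99     # reference discard rule
    min_repeat_len: int = 100
    min_repeat_identity: float = 0.99
    sub_threshold: float = 0.5       # substoichiometric flag
    chimera_min_len: int = 30
    chimera_min_identity: float = 0.9
    probe_min_identity: float = 0.95
    exact_limit: int = 12
    plasmid_max_len: int = 10_000


@dataclass
class RunSummary:
    counts: dict[str, int]
    abundance: list[dict]
    shared_repeats: list[dict]
    gc_percent: dict[str, float]
    amplicons: list[dict]
    config: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    summary: RunSummary
    truth: TruthSet | None
    graph: AssemblyGraph
    structure: GenomeStructure
    orfs: list[OrfRecord]
    raw_orf_count: int
    abundance: list[AbundanceEstimate]
    gene_placements: list
    amplicons: list[Amplicon]
    digests: dict[str, list[DigestFragment]]


def resolve_structure(g: AssemblyGraph, thresholds: Thresholds = Thresholds(),
                      seed: int = 0) -> GenomeStructure:
    """Graph → circles → subgenomes → shared repeats → master hypotheses."""
    circles, linear, mode = decompose_circles(
        g, exact_limit=thresholds.exact_limit, seed=seed)
    structure = merge_subgenomes(circles, g,
                                 plasmid_max_len=thresholds.plasmid_max_len)
    structure.linear_candidates = linear
    structure.search_mode = mode
    structure.ambiguous_orders = enumerate_inverted_orders(structure.circles, g)
    matches = find_shared_repeats(structure, thresholds.min_repeat_len,
                                  thresholds.min_repeat_identity)
    propose_master_circles(structure, matches)
    return structure


def screen_orfs(molecules: dict[str, str], reference: dict[str, str],
                annotations: list[Feature], plasmid_ids: set[str],
                thresholds: Thresholds = Thresholds(),
                ) -> tuple[list[OrfRecord], int]:
    """ORF calling + naming + classification + chimera and TM annotation.

    Returns the annotated records plus the raw open-frame tally (stop-free
    stretches over the peptide floor, the browser-style "predicted orfs"
    count).  ORFs with identical nucleotide sequence are reported once (the
    screen counts distinct orfs); subgenome records take precedence over
    plasmids and over any redundant per-circle records."""
    records: list[OrfRecord] = []
    raw = 0
    seen_orf: set[str] = set()
    seen_raw: set[str] = set()
    mol_order = sorted(molecules, key=lambda m: (not m.startswith("subgenome"),
                                                 not m.startswith("plasmid"), m))
    for mol in mol_order:
        seq = molecules[mol]
        for r in find_orfs(seq, molecule=mol, circular=True,
                           min_aa=thresholds.min_aa):
            if r.seq not in seen_orf:
                seen_orf.add(r.seq)
                records.append(r)
        for r in scan_orfs(seq, molecule=mol, circular=True,
                           min_aa=thresholds.min_aa, require_start=False)[0]:
            if r.seq not in seen_raw:
                seen_raw.add(r.seq)
                raw += 1
    classify_vs_reference(records, reference, thresholds.identity_floor)
    assign_names(records, plasmid_ids)
    genes = gene_sequences(reference, annotations)
    detect_chimeras(records, genes, thresholds.chimera_min_len,
                    thresholds.chimera_min_identity)
    annotate_tm(records)
    return records, raw


def run_pipeline(cfg: SimConfig, outdir: str | Path | None = None,
                 thresholds: Thresholds = Thresholds(),
                 primer_pairs: list[PrimerPair] | str = "fixture",
                 enzyme: tuple[str, str] | None = None,
                 probe: str | None = None,
                 n_boot: int = 0) -> RunResult:
    """Run every stage on a simulated genome and (optionally) write all
    artifacts under ``outdir``.

    With ``primer_pairs="fixture"`` the BoroToy junction primers, EcoRI and
    the recombination probe are derived from the simulated truth, mirroring
    how the study's validation assays were designed from the assembly.
    """
    truth = simulate_genome(cfg)
    contigs, links, depths = fragment_and_observe(truth, cfg)
    reference, annotations, _ = make_reference(truth, cfg)

    g = build_graph(contigs, links, depths.summary)
    estimate_copy_numbers(g, sub_threshold=thresholds.sub_threshold)
    structure = resolve_structure(g, thresholds, seed=cfg.seed)
    gc = compute_gc(structure, g.contigs)

    # stoichiometry of substoichiometric circles
    single_copy = [c for c in sorted(g.contigs)
                   if g.copy_estimate[c] == 1 and c not in g.substoichiometric]
    abundance: list[AbundanceEstimate] = []
    for circ in structure.circles:
        focal = sorted(circ.contig_ids & g.substoichiometric)
        if not focal:
            continue
        depth_src = (depths.per_base if n_boot
                     else {c: g.contigs[c].mean_depth for c in g.contigs})
        abundance.append(estimate_abundance(
            depth_src, focal, single_copy, molecule=circ.id,
            n_boot=n_boot, seed=cfg.seed))

    # ORF screen on the resolved molecules
    molecules = {s.id: s.sequence for s in structure.subgenomes}
    molecules.update({pid: seq for pid, seq in structure.plasmids})
    plasmid_ids = {pid for pid, _ in structure.plasmids}
    orf_records, raw = screen_orfs(molecules, reference, annotations,
                                   plasmid_ids, thresholds)
    gene_placements = annotate_known_genes(
        molecules, reference, annotations, thresholds.identity_floor)

    # in-silico validation
    if primer_pairs == "fixture":
        from .borotoy import ENZYME, junction_primers, recombination_probe
        primer_pairs = [junction_primers(truth)]
        enzyme = enzyme or ENZYME
        probe = probe or recombination_probe(truth)
    amplicons: list[Amplicon] = []
    for pair in primer_pairs or []:
        amplicons.extend(virtual_pcr(molecules, pair))
    digests: dict[str, list[DigestFragment]] = {}
    if enzyme is not None:
        name, site = enzyme
        small = structure.subgenomes[0]
        digests[small.id] = virtual_digest(
            small.id, small.sequence, site, probe=probe,
            probe_min_identity=thresholds.probe_min_identity)
        if structure.master_hypotheses:
            hyp = structure.master_hypotheses[0]
            hid = f"master:{hyp.subgenome_a}+{hyp.subgenome_b}"
            digests[hid] = virtual_digest(
                hid, hyp.sequence, site, probe=probe,
                probe_min_identity=thresholds.probe_min_identity)

    specific = [r for r in orf_records if r.classification == "specific"]
    chimeric = [r for r in specific if r.is_chimeric]
    summary = RunSummary(
        counts={
            "circles": len(structure.circles),
            "subgenomes": len(structure.subgenomes),
            "plasmids": len(structure.plasmids),
            "linear_candidates": len(structure.linear_candidates),
            "raw_orfs": raw,
            "orfs_called": len(orf_records),
            "specific_orfs": len(specific),
            "chimeric_orfs": len(chimeric),
        },
        abundance=[{
            "molecule": a.molecule, "ratio": round(a.ratio, 4),
            "percent": a.percent, "percent_nearest5": a.percent_nearest5,
            "ci_low": round(a.ci_low, 4), "ci_high": round(a.ci_high, 4),
            "method": a.method,
        } for a in abundance],
        shared_repeats=[{
            "molecule_a": m.match.molecule_a, "start_a": m.match.start_a,
            "molecule_b": m.match.molecule_b, "start_b": m.match.start_b,
            "length": m.match.length, "identity": m.match.identity,
            "orientation": m.match.orientation,
            "recombinant_length": m.length,
        } for m in structure.master_hypotheses],
        gc_percent=gc,
        amplicons=[{"molecule": a.molecule, "start": a.start,
                    "length": a.length, "primer_pair": a.primer_pair}
                   for a in amplicons],
        config={
            "seed": cfg.seed, "coverage": cfg.coverage,
            "gc_target": cfg.gc_target, "bridge_rate": cfg.bridge_rate,
            "noise_model": cfg.noise_model,
            "thresholds": dataclasses.asdict(thresholds),
        },
    )

    result = RunResult(summary=summary, truth=truth, graph=g,
                       structure=structure, orfs=orf_records,
                       raw_orf_count=raw, abundance=abundance,
                       gene_placements=gene_placements,
                       amplicons=amplicons, digests=digests)
    if outdir is not None:
        write_artifacts(Path(outdir), result, contigs, links, depths)
    return result


# --------------------------------------------------------------------------
# artifacts

def orfs_dataframe(orfs: list[OrfRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "molecule": r.molecule, "start": r.start, "end": r.end,
        "strand": r.strand, "peptide_length": r.peptide_length,
        "classification": r.classification,
        "chimera_donors": ",".join(h.donor for h in r.chimera_hits) or ".",
        "hydropathy_tm": ";".join(f"{s}-{e}" for s, e in r.tm_segments) or ".",
    } for r in orfs])


def structure_dict(structure: GenomeStructure) -> dict:
    return {
        "circles": [{
            "id": c.id, "order": [str(oc) for oc in c.order],
            "length": c.length, "support": c.support, "abundance": c.abundance,
        } for c in structure.circles],
        "plasmids": [{"id": pid, "length": len(seq)}
                     for pid, seq in structure.plasmids],
        "merge_events": [{"circles": list(pair), "repeat": rid}
                         for pair, rid in structure.merge_events],
        "subgenomes": [{
            "id": s.id, "circles": s.circle_ids, "length": s.length,
            "order": [str(oc) for oc in s.order],
        } for s in structure.subgenomes],
        "master_hypotheses": [{
            "subgenomes": [h.subgenome_a, h.subgenome_b],
            "repeat_length": h.match.length, "length": h.length,
        } for h in structure.master_hypotheses],
        "ambiguous_orders": [{
            "circle": a.circle_id, "primary": a.primary,
            "alternative": a.alternative, "support_ratio": round(a.support_ratio, 4),
            "tie": a.tie,
        } for a in structure.ambiguous_orders],
        "linear_candidates": structure.linear_candidates,
        "search_mode": structure.search_mode,
    }


def write_artifacts(outdir: Path, result: RunResult, contigs, links,
                    depths: DepthProfile) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    from .simulate import write_observations
    if result.truth is not None:
        write_observations(outdir, result.truth, contigs, links, depths)

    structure = result.structure
    mol_seqs: dict[str, str] = {}
    desc: dict[str, str] = {}
    for s in structure.subgenomes:
        mol_seqs[s.id] = s.sequence
        desc[s.id] = f"length={s.length} circles={','.join(s.circle_ids)}"
    for c in structure.circles:
        mol_seqs[c.id] = c.sequence(result.graph.contigs)
        tag = f" abundance={c.abundance}" if c.abundance is not None else ""
        desc[c.id] = f"length={c.length}{tag}"
    for pid, seq in structure.plasmids:
        mol_seqs[pid] = seq
        desc[pid] = f"length={len(seq)}"
    write_fasta(outdir / "molecules.fasta", mol_seqs, desc)

    write_json(outdir / "structure.json", structure_dict(structure))
    pd.DataFrame([{
        "molecule_a": m.molecule_a, "start_a": m.start_a,
        "molecule_b": m.molecule_b, "start_b": m.start_b,
        "length": m.length, "identity": m.identity, "orientation": m.orientation,
    } for m in (h.match for h in structure.master_hypotheses)]).to_csv(
        outdir / "repeats.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "circle": a.circle_id, "primary": a.primary, "alternative": a.alternative,
        "primary_support": a.primary_support,
        "alternative_support": a.alternative_support, "tie": a.tie,
    } for a in structure.ambiguous_orders]).to_csv(
        outdir / "alternatives.tsv", sep="\t", index=False)

    orfs_dataframe(result.orfs).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
    lengths = {mid: len(seq) for mid, seq in mol_seqs.items()}
    feats = [Feature(seqid=r.molecule, type="ORF", start=r.start, end=r.end,
                     strand=r.strand, id=r.id,
                     attributes={"classification": r.classification or ".",
                                 "peptide_length": str(r.peptide_length)})
             for r in result.orfs]
    write_gff3(outdir / "orfs.gff3", feats, lengths)
    write_fasta(outdir / "peptides.fasta",
                {r.id: r.peptide for r in result.orfs})

    pd.DataFrame(result.summary.abundance).to_csv(
        outdir / "abundance.tsv", sep="\t", index=False)
    write_json(outdir / "validation.json", {
        "amplicons": result.summary.amplicons,
        "digests": {mid: [{"start": f.start, "length": f.length,
                           "probe_hit": f.probe_hit, "uncut": f.uncut}
                          for f in frags]
                    for mid, frags in result.digests.items()},
    })
    write_json(outdir / "summary.json", result.summary.to_dict())


def load_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
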
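"""The BoroToy fixture: a five-chromosome multipartite mitogenome emulating
the Boro-type CMS rice study system at full scale.

Structure (~550 kb total):

* MC-1 (95 kb, c0002+c0003) — alone it forms subgenome-1.
* MC-2 (142 kb), MC-3 (54 kb, at 0.1 abundance, carrying the N-atp6 flank
  segment c0043 between inverted copies of c0032), MC-4 (157 kb) and MC-5
  (100 kb) share the high-depth repeat segments c0032 (MC-2/3/4) and c0026
  (MC-2/4/5) and merge into subgenome-2 (~453 kb).
* Four plasmid-like molecules B1–B4 (2,135 / 1,548 / 1,514 / 969 bp) with
  the GC contents reported for them (44.2 / 42.9 / 42.1 / 49.8%).
* A 450-bp identical block shared between the c0002/c0003 junction
  (subgenome-1) and the interior of c0015 (subgenome-2) — the master-circle
  recombination substrate.  Flanking bases are pinned so the shared block is
  maximal at exactly 450 bp.
* 17 planted mitochondria-specific ORFs (12 chromosomal, 5 plasmid-borne),
  absent from the matched reference; four are chimeric: cob→orf449,
  orf288→orf310, atp4→orf97 and coxI→orf79 (which also carries a
  transmembrane stretch).  Known genes (chimera donors, atp6 in both its
  B- and N-type contexts, and the trans-spliced nad1/nad5 exon sets split
  across the two subgenomes) are planted identically in genome and
  reference.
* An engineered EcoRI map around the shared block: digesting subgenome-1
  releases a 1.5-kb probe-bearing fragment; digesting the predicted
  master-circle recombinant releases a 1.3-kb one.

The bridge-link rate is 2.0 spanning pairs per unit coverage — an 8-kb
paired-end library physically covers each junction far more often than base
coverage alone — so the 0.1-abundance MC-3 junctions retain non-zero
support.
"""

from __future__ import annotations

from .simulate import (CircleSpec, GeneSpec, PlantedOrf, PlasmidSpec, SharedBlock,
                       SimConfig, TruthSet)
from ._seq import revcomp
from .validate import PrimerPair

ENZYME = ("EcoRI", "GAATTC")

SEGMENTS = {
    "c0002": 50_000, "c0003": 45_000,           # MC-1 / subgenome-1
    "c0006": 30_000, "c0007": 35_000, "c0015": 70_000,   # MC-2
    "c0020": 70_000, "c0021": 80_000,           # MC-4
    "c0026": 3_000,                             # repeat: MC-2 / MC-4 / MC-5
    "c0031": 8_000, "c0043": 3_000,             # MC-3 only (substoichiometric)
    "c0032": 4_000,                             # repeat: MC-2 / MC-3 (x2) / MC-4
    "c0050": 97_000,                            # MC-5
}

# engineered coordinates around the 450-bp shared block
_BLOCK_C0002 = 50_000 - 450     # block is the last 450 bp of c0002
_BLOCK_C0015 = 55_000
_ECO_C0002 = 50_000 - 1_200     # EcoRI 1,200 bp before the c0002/c0003 junction
_ECO_C0003 = 300                # ... 300 bp into c0003 (subgenome-1: 1.5-kb fragment)
_ECO_C0015 = _BLOCK_C0015 + 450 + 100   # 100 bp past the block (recombinant: 1.3 kb)
_PROBE_SPAN = (50_000 - 1_050, 50_000 - 850)  # 200-bp probe on c0002

_PRIMER_F_SPAN = (1_350, 1_370)   # on c0026, 1,630 bp before its tail junction
_PRIMER_R_SPAN = (1_630, 1_650)   # on c0006 (reverse primer binds here)
JUNCTION_PRODUCT = 7_300          # 1,650 + 4,000 (c0032) + 1,650


def borotoy_config(seed: int = 0) -> SimConfig:
    """The fixture configuration; only the seed varies."""
    return SimConfig(
        seed=seed,
        segments=dict(SEGMENTS),
        circles=[
            CircleSpec("MC-1", (("c0002", "+"), ("c0003", "+"))),
            CircleSpec("MC-2", (("c0032", "+"), ("c0006", "+"), ("c0007", "+"),
                                ("c0015", "+"), ("c0026", "+"))),
            CircleSpec("MC-3", (("c0032", "+"), ("c0031", "+"), ("c0007", "+"),
                                ("c0043", "+"), ("c0032", "-")),
                       copy_number=0.1, isomer_fraction=0.2),
            CircleSpec("MC-4", (("c0032", "+"), ("c0020", "+"), ("c0026", "+"),
                                ("c0021", "+"))),
            CircleSpec("MC-5", (("c0026", "+"), ("c0050", "+"))),
        ],
        plasmids=[
            PlasmidSpec("B1", 2_135, gc=0.442),
            PlasmidSpec("B2", 1_548, gc=0.429),
            PlasmidSpec("B3", 1_514, gc=0.421),
            PlasmidSpec("B4", 969, gc=0.498),
        ],
        coverage=50.0,
        gc_target=0.44,
        bridge_rate=2.0,
        shared_blocks=[SharedBlock("sub_rec", 450,
                                   (("c0002", _BLOCK_C0002),
                                    ("c0015", _BLOCK_C0015)))],
        # pin the block flanks so the shared sequence is maximal at 450 bp
        base_edits=[("c0002", _BLOCK_C0002 - 1, "A"),
                    ("c0015", _BLOCK_C0015 - 1, "C"),
                    ("c0003", 0, "G"),
                    ("c0015", _BLOCK_C0015 + 450, "T")],
        motif_free_windows=[("c0002", 48_700, 50_000, "GAATTC"),
                            ("c0003", 0, 400, "GAATTC"),
                            ("c0015", 54_900, 55_650, "GAATTC")],
        motif_plants=[("c0002", _ECO_C0002, "GAATTC"),
                      ("c0003", _ECO_C0003, "GAATTC"),
                      ("c0015", _ECO_C0015, "GAATTC")],
        genes=[
            GeneSpec("coxI", (("c0006", 2_000, 1_584),)),
            GeneSpec("ccmFc", (("c0006", 8_000, 1_320),)),
            GeneSpec("atp6", (("c0007", 5_000, 780),),
                     copy_to=(("c0043", 500),)),     # N-atp6 duplicate locus
            GeneSpec("cob", (("c0021", 10_000, 1_182),)),
            GeneSpec("atp4", (("c0020", 20_000, 591),)),
            GeneSpec("orf288", (("c0015", 30_000, 867),)),
            GeneSpec("nad1", (("c0002", 10_000, 387),    # exon 1 in subgenome-1
                              ("c0020", 40_000, 300),
                              ("c0020", 42_000, 192),
                              ("c0021", 30_000, 252),
                              ("c0021", 33_000, 258)), coding=False),
            GeneSpec("nad5", (("c0003", 10_000, 350),    # exons 1-2 in subgenome-1
                              ("c0003", 12_000, 301),
                              ("c0050", 20_000, 250),
                              ("c0050", 22_000, 301),
                              ("c0050", 24_000, 400)), coding=False),
        ],
        planted_orfs=[
            # chromosomal (all on subgenome-2 molecules)
            PlantedOrf("orf74", 74, "c0015", 5_000),
            PlantedOrf("orf76", 76, "c0006", 14_000),
            PlantedOrf("orf79", 79, "c0006", 16_000,
                       chimera=("coxI", 0.4), tm_segment=True),
            PlantedOrf("orf82", 82, "c0006", 18_000, strand="-"),
            PlantedOrf("orf83", 83, "c0015", 8_000),
            PlantedOrf("orf88", 88, "c0020", 5_000),
            PlantedOrf("orf97", 97, "c0020", 8_000, chimera=("atp4", 0.4)),
            PlantedOrf("orf108", 108, "c0006", 20_000),
            PlantedOrf("orf115", 115, "c0021", 5_000, strand="-"),
            PlantedOrf("orf128", 128, "c0021", 8_000),
            PlantedOrf("orf310", 310, "c0050", 5_000, chimera=("orf288", 0.55)),
            PlantedOrf("orf449", 449, "c0050", 10_000, chimera=("cob", 0.5)),
            # plasmid-borne
            PlantedOrf("orf80_B1", 80, "B1", 100),
            PlantedOrf("orf95_B1", 95, "B1", 600),
            PlantedOrf("orf138_B2", 138, "B2", 200),
            PlantedOrf("orf73_B3", 73, "B3", 300),
            PlantedOrf("orf83_B4", 83, "B4", 200),
        ],
    )


SPECIFIC_ORF_COUNT = 17
CHIMERIC_ORFS = {"orf449": "cob", "orf310": "orf288", "orf97": "atp4",
                 "orf79": "coxI"}


def junction_primers(truth: TruthSet) -> PrimerPair:
    """The fixture's c0032-junction primer pair (7B/8A analogue): forward in
    c0026, reverse in c0006, flanking the c0026→c0032→c0006 connection of
    MC-2; product 7,300 bp on any molecule carrying that junction."""
    fwd = truth.segment_sequences["c0026"][slice(*_PRIMER_F_SPAN)]
    rev_site = truth.segment_sequences["c0006"][slice(*_PRIMER_R_SPAN)]
    return PrimerPair("jxn_c0032", fwd, revcomp(rev_site), max_product=8_000)


def recombination_probe(truth: TruthSet) -> str:
    """The Southern probe adjacent to the shared 450-bp block on the
    subgenome-1 side (sub1_rec analogue)."""
    return truth.segment_sequences["c0002"][slice(*_PROBE_SPAN)]
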
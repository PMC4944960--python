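import numpy as np
import pytest

from mitomosaic._seq import STOP_CODONS, random_dna, random_orf_codons, revcomp
from mitomosaic.orfs import (OrfInputError, OrfRecord, assign_names,
                             classify_vs_reference, detect_chimeras, find_orfs,
                             predict_tm, scan_orfs)


def orf_of(n_codons, rng=None):
    rng = rng or np.random.default_rng(1)
    return "ATG" + random_orf_codons(rng, n_codons, 0.44) + "TAA"


# --------------------------------------------------------------------------
# six-frame calling

def test_peptide_floor_is_a_hard_boundary():
    """ATG + 69 sense codons + stop encodes 70 aa and is retained at the
    70-aa floor; one codon fewer is dropped."""
    keep = "CCC" + orf_of(69) + "CCC"
    drop = "CCC" + orf_of(68) + "CCC"
    assert [r.peptide_length for r in find_orfs(keep, circular=False)] == [70]
    assert find_orfs(drop, circular=False) == []


def oracle_six_frame(seq, min_aa, circular):
    """Position-by-position reference ORF scan: for every frame on both
    strands, every stop, take the first ATG after the previous stop."""
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        text = s + s if circular else s
        for f in range(3):
            prev_stop = None
            atg = None
            for i in range(f, len(text) - 2, 3):
                cod = text[i:i + 3]
                if cod in STOP_CODONS:
                    if atg is not None and (i - atg) // 3 >= min_aa:
                        start, ln = atg, i + 3 - atg
                        if not circular or (start < L and ln <= L):
                            if strand == "+":
                                fstart = start
                            elif circular:
                                fstart = (L - ((start + ln) % L)) % L
                            else:
                                fstart = L - start - ln
                            out.add((fstart, ln, strand))
                    atg = None
                    prev_stop = i
                elif cod == "ATG" and atg is None:
                    atg = i
    return out


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("circular", [False, True])
def test_six_frame_scan_matches_bruteforce_oracle(seed, circular):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 5000, 0.44)
    got = {(r.start, r.end - r.start, r.strand)
           for r in find_orfs(seq, min_aa=20, circular=circular)}
    assert got == oracle_six_frame(seq, 20, circular)


def test_strand_symmetry(rng):
    seq = random_dna(rng, 4000, 0.44)
    fwd = find_orfs(seq, min_aa=20, circular=False)
    rev = find_orfs(revcomp(seq), min_aa=20, circular=False)
    L = len(seq)
    mirrored = {(L - r.end, L - r.start, "+-"[r.strand == "+"]) for r in rev}
    assert {(r.start, r.end, r.strand) for r in fwd} == mirrored


def test_raising_min_aa_never_adds_orfs(rng):
    seq = random_dna(rng, 6000, 0.44)
    lower = {(r.start, r.end, r.strand) for r in find_orfs(seq, min_aa=20)}
    higher = {(r.start, r.end, r.strand) for r in find_orfs(seq, min_aa=40)}
    assert higher <= lower


def test_origin_wrapping_orf_is_found_once():
    core = orf_of(75)
    # place the ORF across the circular origin
    seq = core[100:] + "CCCTAACCC" + core[:100]
    hits = [r for r in find_orfs(seq, circular=True) if r.end > len(seq) - 100]
    wrapped = [r for r in hits if r.end > len(seq)]
    assert len(wrapped) == 1
    r = wrapped[0]
    assert (seq + seq)[r.start:r.end] == core
    assert find_orfs(seq, circular=False) == []


def test_orfs_containing_n_are_skipped_and_counted():
    core = list(orf_of(80))
    core[30] = "N"
    records, skipped = scan_orfs("CCC" + "".join(core) + "CCC", circular=False)
    assert records == []
    assert skipped == 1


def test_non_dna_alphabet_is_an_input_error():
    with pytest.raises(OrfInputError):
        find_orfs("ACGTQ")


def test_open_frame_mode_counts_stop_free_stretches():
    seq = "TAA" + "GCT" * 80 + "TAG"
    no_start = find_orfs(seq, circular=False, min_aa=70, require_start=False)
    with_start = find_orfs(seq, circular=False, min_aa=70)
    assert len(no_start) == 1 and with_start == []


# --------------------------------------------------------------------------
# classification

def test_verbatim_reference_copy_is_common(rng):
    orf = orf_of(80, rng)
    ref = {"NB": random_dna(rng, 2000, 0.44) + orf + random_dna(rng, 2000, 0.44)}
    rec = OrfRecord("x", "m", 0, len(orf), "+", 80, orf)
    classify_vs_reference([rec], ref)
    assert rec.classification == "common"
    # reverse-strand copies count too
    rec2 = OrfRecord("y", "m", 0, len(orf), "+", 80, revcomp(orf))
    classify_vs_reference([rec2], ref)
    assert rec2.classification == "common"


def test_two_percent_wobble_divergence_stays_common(rng):
    """>99% nucleotide identity: mutating 2% of codons at the wobble
    position (0.67% of sites) keeps the ORF below the discard threshold."""
    orf = orf_of(100, rng)
    mutated = list(orf)
    picks = rng.choice(np.arange(1, 99), size=2, replace=False)
    for c in picks:
        pos = 3 * c + 2
        mutated[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutated[pos]]
    ref = {"NB": random_dna(rng, 1000, 0.44) + "".join(mutated)
           + random_dna(rng, 1000, 0.44)}
    rec = OrfRecord("x", "m", 0, len(orf), "+", 100, orf)
    classify_vs_reference([rec], ref)
    assert rec.classification == "common"


def test_three_percent_divergence_is_specific(rng):
    orf = orf_of(100, rng)
    mutated = list(orf)
    for pos in rng.choice(np.arange(3, len(orf) - 3), size=int(0.03 * len(orf)),
                          replace=False):
        mutated[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutated[pos]]
    ref = {"NB": "".join(mutated)}
    rec = OrfRecord("x", "m", 0, len(orf), "+", 100, orf)
    classify_vs_reference([rec], ref)
    assert rec.classification == "specific"


def test_empty_reference_is_an_input_error():
    rec = OrfRecord("x", "m", 0, 10, "+", 2, "ATGAAATAA")
    with pytest.raises(OrfInputError, match="empty reference"):
        classify_vs_reference([rec], {})


# --------------------------------------------------------------------------
# chimeras

def test_constructed_chimera_is_flagged(rng):
    gene = orf_of(200, rng)
    orf_seq = "ATG" + gene[60:120] + random_orf_codons(rng, 50, 0.44) + "TAA"
    rec = OrfRecord("x", "m", 0, len(orf_seq), "+", len(orf_seq) // 3 - 1,
                    orf_seq, classification="specific")
    detect_chimeras([rec], {"geneX": gene})
    assert rec.is_chimeric
    hit = rec.chimera_hits[0]
    assert hit.donor == "geneX"
    assert hit.length >= 60
    assert hit.identity >= 0.9


def test_fully_novel_orf_has_no_chimera_hits():
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        genes = {"g": random_dna(rng, 100_000, 0.44)}
        rec = OrfRecord("x", "m", 0, 303, "+", 100, orf_of(100, rng),
                        classification="specific")
        detect_chimeras([rec], genes)
        assert rec.chimera_hits == []


def test_full_length_gene_match_is_not_chimeric(rng):
    gene = orf_of(100, rng)
    rec = OrfRecord("x", "m", 0, len(gene), "+", 100, gene,
                    classification="specific")
    detect_chimeras([rec], {"g": gene})
    assert not rec.is_chimeric  # covers 100% of the ORF: common-type, not chimera


# --------------------------------------------------------------------------
# transmembrane segments

def test_poly_isoleucine_gives_one_segment():
    assert predict_tm("I" * 30) == [(0, 30)]


def test_poly_aspartate_gives_none():
    assert predict_tm("D" * 30) == []


def test_short_peptide_gives_empty_list_not_error():
    assert predict_tm("MKV") == []


@pytest.mark.parametrize("seed", range(5))
def test_tm_segments_match_windowed_mean_oracle(seed):
    rng = np.random.default_rng(seed)
    from mitomosaic._seq import KYTE_DOOLITTLE
    aas = list(KYTE_DOOLITTLE)
    pep = "".join(rng.choice(aas, 120)) + "I" * 25 + "".join(rng.choice(aas, 30))
    segs = predict_tm(pep)
    hot = set()
    for i in range(len(pep) - 18):
        if np.mean([KYTE_DOOLITTLE[a] for a in pep[i:i + 19]]) > 1.6:
            hot |= set(range(i, i + 19))
    assert set().union(*(range(s, e) for s, e in segs)) == hot if segs else not hot
    assert all(e - s >= 19 for s, e in segs)


# --------------------------------------------------------------------------
# naming

def test_orf_naming_by_length_with_plasmid_suffix_and_collisions():
    recs = [OrfRecord("", "subgenome-2", 0, 10, "+", 83, "A", "specific"),
            OrfRecord("", "plasmid-4", 0, 10, "+", 83, "C", "specific"),
            OrfRecord("", "subgenome-2", 50, 60, "+", 83, "G", "common"),
            OrfRecord("", "plasmid-1", 0, 10, "+", 80, "T", "specific")]
    assign_names(recs, {"plasmid-1", "plasmid-4"})
    names = {r.seq: r.id for r in recs}
    assert names["A"] == "orf83"          # chromosomal specific keeps base name
    assert names["C"] == "orf83_plasmid-4"  # plasmid-borne always suffixed
    assert names["T"] == "orf80_plasmid-1"
    assert names["G"].startswith("orf83_subgenome-2")  # collision suffix
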
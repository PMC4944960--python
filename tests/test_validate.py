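import numpy as np
import pytest

from mitomosaic._seq import random_dna, revcomp
from mitomosaic.validate import (PrimerError, PrimerPair, virtual_digest,
                                 virtual_pcr)


def pair_at(seq, f_start, r_end, name="p", max_product=5000, lp=20):
    fwd = seq[f_start:f_start + lp]
    rev = revcomp(seq[r_end - lp:r_end])
    return PrimerPair(name, fwd, rev, max_product)


def test_linear_molecule_single_amplicon_exact_coordinates(rng):
    seq = random_dna(rng, 1000, 0.5)
    pair = pair_at(seq, 100, 620)
    amps = virtual_pcr({"m": seq}, pair, circular=False)
    assert [(a.start, a.end, a.length) for a in amps] == [(100, 620, 520)]


def test_non_convergent_primers_give_no_product(rng):
    seq = random_dna(rng, 1000, 0.5)
    # both primers on the same strand orientation: no convergence
    pair = PrimerPair("p", seq[100:120], seq[600:620], 5000)
    assert virtual_pcr({"m": seq}, pair, circular=False) == []


def test_product_ceiling_is_enforced(rng):
    seq = random_dna(rng, 2000, 0.5)
    pair = pair_at(seq, 100, 1900, max_product=1000)
    assert virtual_pcr({"m": seq}, pair, circular=False) == []


def test_amplicon_set_invariant_under_reverse_complement(rng):
    seq = random_dna(rng, 3000, 0.5)
    pair = pair_at(seq, 400, 1400)
    a1 = virtual_pcr({"m": seq}, pair, circular=False)
    a2 = virtual_pcr({"m": revcomp(seq)}, pair, circular=False)
    assert sorted(a.length for a in a1) == sorted(a.length for a in a2) == [1000]


def test_origin_wrapping_amplicon(rng):
    seq = random_dna(rng, 2000, 0.5)
    fwd = seq[1800:1820]
    rev = revcomp((seq + seq)[2280:2300])
    pair = PrimerPair("w", fwd, rev, 1000)
    amps = virtual_pcr({"m": seq}, pair, circular=True)
    assert [(a.start, a.length) for a in amps] == [(1800, 500)]


def test_three_prime_anchor_blocks_terminal_mismatch(rng):
    seq = random_dna(rng, 1000, 0.5)
    fwd = list(seq[100:120])
    fwd[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[-1]]  # 3' mismatch
    pair = PrimerPair("p", "".join(fwd), revcomp(seq[600:620]), 5000)
    assert virtual_pcr({"m": seq}, pair, max_mismatch=1, circular=False) == []
    # the same single mismatch away from the 3' end is tolerated
    fwd2 = list(seq[100:120])
    fwd2[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd2[5]]
    pair2 = PrimerPair("p", "".join(fwd2), revcomp(seq[600:620]), 5000)
    assert len(virtual_pcr({"m": seq}, pair2, max_mismatch=1,
                           circular=False)) == 1


def test_iupac_degenerate_primer_matches_expansion(rng):
    seq = random_dna(rng, 600, 0.5)
    fwd = list(seq[50:70])
    fwd[4] = "N"
    fwd[8] = {"A": "R", "G": "R", "C": "Y", "T": "Y"}[fwd[8]]
    pair = PrimerPair("p", "".join(fwd), revcomp(seq[400:420]), 1000)
    assert len(virtual_pcr({"m": seq}, pair, circular=False)) == 1


def test_non_iupac_primer_is_an_input_error():
    with pytest.raises(PrimerError, match="non-IUPAC"):
        PrimerPair("p", "ACGTACGTACGTACGQ", "ACGTACGTACGTACGT", 100)


def test_pcr_sites_match_string_scan_oracle(rng):
    """Every amplicon corresponds to a naive all-positions scan for the
    forward primer and the reverse primer's reverse complement."""
    seq = random_dna(rng, 20000, 0.5)
    pair = pair_at(seq, 5000, 9000, max_product=6000)
    amps = virtual_pcr({"m": seq}, pair, circular=False)
    f_sites = [i for i in range(len(seq) - 19) if seq[i:i + 20] == pair.fwd]
    r_sites = [i for i in range(len(seq) - 19)
               if seq[i:i + 20] == revcomp(pair.rev)]
    expect = sorted((a, b + 20 - a) for a in f_sites for b in r_sites
                    if b >= a and b + 20 - a <= 6000)
    assert sorted((a.start, a.length) for a in amps) == expect


# --------------------------------------------------------------------------
# digestion

def test_circular_two_sites_two_fragments_conserving_length(rng):
    body = random_dna(rng, 10000, 0.5).replace("GAATTC", "GAATTG")
    seq = body[:3000] + "GAATTC" + body[3000:7000] + "GAATTC" + body[7000:9988]
    frags = virtual_digest("m", seq, "GAATTC")
    assert len(frags) == 2
    assert sum(f.length for f in frags) == len(seq)


def test_absent_site_gives_single_uncut_fragment(rng):
    seq = random_dna(rng, 5000, 0.5).replace("GAATTC", "GAATTG")
    frags = virtual_digest("m", seq, "GAATTC")
    assert len(frags) == 1 and frags[0].uncut and frags[0].length == len(seq)


def test_non_palindromic_site_cuts_both_strands(rng):
    body = random_dna(rng, 4000, 0.5)
    site = "GGTCTC"  # BsaI-like, non-palindromic
    clean = body.replace(site, "GGTCTG").replace(revcomp(site), "GAGACG")
    seq = clean[:1000] + site + clean[1000:2000] + revcomp(site) + clean[2000:3988]
    frags = virtual_digest("m", seq, site)
    assert len(frags) == 2
    assert sum(f.length for f in frags) == len(seq)


@pytest.mark.parametrize("seed", range(5))
def test_digest_positions_match_string_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 20000, 0.5)
    frags = virtual_digest("m", seq, "GAATTC")
    expect = sorted(i for i in range(len(seq) - 5) if seq[i:i + 6] == "GAATTC")
    if not expect:
        assert len(frags) == 1 and frags[0].uncut
    else:
        assert sorted(f.start for f in frags) == expect
        assert sum(f.length for f in frags) == len(seq)


def test_probe_hybridises_at_full_length_95_percent(rng):
    seq = random_dna(rng, 6000, 0.5).replace("GAATTC", "GAATTG")
    probe = seq[1200:1400]
    seq = seq[:1000] + "GAATTC" + seq[1006:3000] + "GAATTC" + seq[3006:]
    frags = virtual_digest("m", seq, "GAATTC", probe=probe)
    hits = [f for f in frags if f.probe_hit]
    assert len(hits) == 1
    assert hits[0].start <= 1200 < hits[0].end


def test_short_recognition_sequence_is_rejected():
    with pytest.raises(PrimerError, match=">= 4"):
        virtual_digest("m", "ACGTACGT", "ACG")
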
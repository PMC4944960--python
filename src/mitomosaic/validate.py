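"""In-silico recasts of the wet-lab confirmations: virtual PCR across
predicted junctions and virtual restriction digestion with probe-fragment
prediction.

Virtual PCR reports every convergent forward/reverse primer site pair within
the product ceiling, on both strands and across the circular origin.  Primer
matching is exact by default; IUPAC degeneracy is expanded, and mismatches
(when allowed) are forbidden in the three 3'-terminal bases, since extension
requires 3' complementarity.

Virtual digestion cuts at every recognition-site occurrence on either strand
(palindromic sites counted once); the fragments tile the molecule exactly.
A probe "hybridises" to a fragment when it aligns full-length at ≥ 95%
identity on either strand — a stringency stand-in, with no thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import IUPAC, revcomp


class PrimerError(ValueError):
    pass


@dataclass
class PrimerPair:
    name: str
    fwd: str
    rev: str
    max_product: int

    def __post_init__(self):
        self.fwd = self.fwd.upper()
        self.rev = self.rev.upper()
        for p in (self.fwd, self.rev):
            bad = set(p) - set(IUPAC)
            if bad:
                raise PrimerError(f"primer {self.name}: non-IUPAC characters {sorted(bad)}")
            if len(p) < 15:
                raise PrimerError(f"primer {self.name}: primers must be >= 15 nt")
        if self.max_product <= 0:
            raise PrimerError(f"primer {self.name}: max_product must be > 0")


@dataclass
class Amplicon:
    molecule: str
    start: int      # 0-based; end may exceed molecule length (origin wrap)
    end: int
    length: int
    primer_pair: str


@dataclass
class DigestFragment:
    molecule: str
    start: int
    end: int
    length: int
    probe_hit: bool
    uncut: bool = False


# --------------------------------------------------------------------------

_BASES = "ACGTN"
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _primer_profile(primer: str) -> np.ndarray:
    """(len, 5) boolean table: allowed bases per primer position (N in the
    template never matches)."""
    prof = np.zeros((len(primer), 5), dtype=bool)
    for i, ch in enumerate(primer):
        for b in IUPAC[ch]:
            prof[i, _BASES.index(b)] = True
    return prof


def _match_sites(text_codes: np.ndarray, primer: str, max_mismatch: int,
                 anchor_positions: range) -> np.ndarray:
    """Start positions where the primer matches with <= max_mismatch
    mismatches and none at the anchor positions (primer coordinates)."""
    lp = len(primer)
    n = len(text_codes) - lp + 1
    if n <= 0:
        return np.zeros(0, dtype=int)
    prof = _primer_profile(primer)
    mism = np.zeros(n, dtype=np.int16)
    anchor_bad = np.zeros(n, dtype=bool)
    for i in range(lp):
        ok = prof[i][text_codes[i:i + n]]
        mism += ~ok
        if i in anchor_positions:
            anchor_bad |= ~ok
    return np.flatnonzero((mism <= max_mismatch) & ~anchor_bad)


def virtual_pcr(molecules: dict[str, str], pair: PrimerPair,
                max_mismatch: int = 0, circular: bool = True,
                ) -> list[Amplicon]:
    """All products of the primer pair on every molecule.

    A product arises wherever a forward-primer site and a downstream
    reverse-primer site converge within ``max_product``; both template
    strands are considered, so the result is invariant under reverse
    complementing a molecule.
    """
    out: list[Amplicon] = []
    for mol in sorted(molecules):
        seq = molecules[mol].upper()
        L = len(seq)
        text = seq + seq if circular else seq
        codes = _ENC[np.frombuffer(text.encode(), dtype=np.uint8)]
        lim = min(pair.max_product, L) if circular else pair.max_product

        def products(p_left: str, p_right: str):
            """p_left anneals to the plus strand (3' end at its right); the
            reverse partner's site is the reverse complement of p_right."""
            lf, lr = len(p_left), len(p_right)
            f_sites = _match_sites(codes, p_left, max_mismatch,
                                   range(lf - 3, lf))
            r_site_seq = revcomp(p_right)
            # the right primer's 3' end maps to the site's first bases
            r_sites = _match_sites(codes, r_site_seq, max_mismatch, range(0, 3))
            for a in f_sites:
                if a >= L:
                    continue
                for b in r_sites:
                    if b < a:
                        continue
                    product = b + lr - a
                    if product > lim:
                        continue
                    if product < max(lf, lr):
                        continue
                    yield int(a), int(product)

        seen = set()
        for a, product in products(pair.fwd, pair.rev):
            key = (a % L, product)
            if key not in seen:
                seen.add(key)
                out.append(Amplicon(mol, a % L, a % L + product, product, pair.name))
        for a, product in products(pair.rev, pair.fwd):
            # the forward primer sits on the right, reading the minus strand
            key = (a % L, product)
            if key not in seen:
                seen.add(key)
                out.append(Amplicon(mol, a % L, a % L + product, product, pair.name))
    out.sort(key=lambda a: (a.molecule, a.start, a.length))
    return out


# --------------------------------------------------------------------------

def virtual_digest(molecule_id: str, seq: str, site: str,
                   probe: str | None = None, circular: bool = True,
                   probe_min_identity: float = 0.95) -> list[DigestFragment]:
    """Fragments of a restriction digest, tiling the molecule exactly.

    Circular molecules with n sites give n fragments; with none, the whole
    molecule is returned flagged uncut.  Cuts are placed at recognition-site
    starts (overhang geometry is not modelled).
    """
    site = site.upper()
    if len(site) < 4:
        raise PrimerError("recognition sequence must be >= 4 nt")
    seq = seq.upper()
    L = len(seq)
    text = seq + seq[:len(site) - 1] if circular else seq

    cuts = set()
    for s in {site, revcomp(site)}:
        start = text.find(s)
        while start != -1:
            if start < L:
                cuts.add(start)
            start = text.find(s, start + 1)
    cuts = sorted(cuts)

    def hit(frag: str) -> bool:
        if probe is None or len(frag) < 1:
            return False
        k = int(len(probe) * (1 - probe_min_identity))
        for q in (probe.upper(), revcomp(probe.upper())):
            res = edlib.align(q, frag, mode="HW", task="distance", k=k)
            if res["editDistance"] != -1:
                return True
        return False

    if not cuts:
        return [DigestFragment(molecule_id, 0, L, L, hit(seq), uncut=True)]

    frags: list[DigestFragment] = []
    if circular:
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            end = nxt if nxt > c else nxt + L
            frag_seq = (seq + seq)[c:end]
            frags.append(DigestFragment(molecule_id, c, end, end - c, hit(frag_seq)))
    else:
        bounds = [0] + cuts + [L]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                frags.append(DigestFragment(molecule_id, a, b, b - a, hit(seq[a:b])))
    return frags
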
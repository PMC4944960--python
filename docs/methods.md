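# Methods

## The model

Plant mitochondrial genomes are treated as **multipartite collections of
circular molecules over a shared contig alphabet**.  A contig is a sequenced
segment with a mean read depth; bridge evidence (paired-end spans) is
abstracted as undirected links between contig *ends* (head = 5′ of the
stored strand, tail = 3′), so a link encodes the relative orientation of an
adjacency but not long-range phasing.  Molecules are closed walks
alternating contig traversals and links; read depth of a contig is
proportional to the summed copy number of the molecules that carry it.

This abstraction deliberately matches what short/medium-read assemblies of
organelle genomes provide, and inherits their ambiguities: configurations
that differ only in the pairing of identical repeat copies have identical
link evidence (see "Known limitations").

## Copy-number estimation

Baseline depth *d₀* is the median of the contigs lying within ±35% of the
overall median depth — the dominant single-copy mode, robust to a minority
of repeats (high depth) and substoichiometric contigs (low depth).  Copy
estimate is `max(1, round(d/d₀))`; contigs with `d/d₀ < 0.5` (default) are
flagged substoichiometric and keep estimate 1, since low depth there means
a rare *molecule*, not a fractional copy.  Both thresholds are parameters
of `estimate_copy_numbers` and of the pipeline `Thresholds`.  The estimate
is invariant under uniform depth rescaling; on simulated data it recovers
true copy sums ≤ 4 essentially always at 50× coverage and ≥ 5-kb contigs.

## Parsimonious circle decomposition

The reconstruction principle is parsimony: *every contig appears at least
once in the smallest genome consistent with the link evidence*.  Formally,
choose multiplicities `m_c ∈ [1, cap_c]` and link-use counts `t_l ≥ 0` with
the balance condition that each contig end is used exactly `m_c` times,
minimising `Σ m_c·len_c`; ties are broken toward higher total used link
support.  This is solved exactly as a small integer program
(`scipy.optimize.milp`); instances here have tens of variables.

Given `(m, t)`, the multigraph decomposes into circles by pairing, at each
contig, head-uses with tail-uses.  Different pairings yield different circle
sets of identical total length; we enumerate pairings exhaustively while the
number of alternatives is within `exact_limit` (default 12; the mode is
recorded in the output) and otherwise use seeded greedy restarts.  Among
pairings we prefer (1) the most circles, then (2) the smallest maximal
circle, then (3) the lexicographically smallest canonical forms.  The first
two criteria encode the observation that large organelle chromosomes favour
subdivision by repeat-mediated recombination, so the fully subdivided state
is the primary presentation; the third makes results reproducible.
Contigs with a linkless end cannot close and are reported as linear
candidates, never forced circular (minor genome forms may well be linear);
an infeasible remainder raises a structural error naming the contigs.

**Substoichiometric pass.**  Flagged contigs are excluded from the main
cover (their molecules are not part of the "smallest genome") and closed in
a second pass that may borrow backbone contigs (≤ 2 extra uses each).  The
resulting circles carry an abundance tag — the mean depth ratio of their
flagged contigs — and represent coexisting minor isoforms.

**Canonical form.**  A circle is rotated to start at its lexicographically
smallest contig id in '+' orientation (or '−' if '+' never occurs) and
traversed in the direction with the smaller order string; all structural
comparisons use this form.

## Subgenome merging and master circles

Circles sharing a multi-copy contig (`copy ≥ 2`) are unioned transitively
into subgenomes, numbered by ascending length.  The merged circular
sequence is built by *repeat-mediated insertion*: the next circle is rotated
to start at the shared repeat and spliced in at the last occurrence of that
repeat in the accumulated order, leaving two repeat copies, one per former
junction.  Every adjacency of every member circle survives this operation;
splicing at the most recently created copy also keeps earlier three-contig
contexts (and hence junction-spanning PCR products) intact.

Maximal near-identical sequences shared **between** subgenomes are found by
dense, exact 31-mer anchoring (2-bit packed, collision-free) merged along
diagonals into maximal exact runs, then chained across small gaps while the
combined identity stays above the floor (defaults: ≥ 100 bp, ≥ 0.99).
Circularity is handled by sequence doubling with modular deduplication.
Each inter-subgenome match yields one **master-circle hypothesis**: the
single-reciprocal-crossover recombinant (both repeat copies retained, one
per former junction, so its length is the sum of the two subgenomes),
reported with its predicted sequence but never promoted to an observed
molecule.

**Inverted-repeat order alternatives.**  For a circle carrying the same
contig in both orientations, the flipped-block order is emitted alongside
the primary, with the summed junction-link support of each phasing as the
discriminator (the in-silico surrogate for relative PCR band intensity).
For a *perfect* inverted repeat pair the two phasings generate identical
undirected end-pair multisets — and when the circle is exactly
repeat + block, the flipped order is the reverse complement of the primary,
i.e. the same molecule — so such alternatives are reported with a tie flag
rather than an arbitrary resolution.

## Stoichiometry

Abundance of a minor configuration = mean depth over its diagnostic
(focal) contigs ÷ mean over single-copy reference contigs, aggregating
per-contig means unweighted by default (the analysis contrasts per-contig
values; length weighting is a flag).  With per-base depths, a seeded
bootstrap (1,000 position resamples per contig) gives the 95% interval;
with only totals, a Poisson delta-method interval on the log ratio
(`var ≈ 1/ΣD_f + 1/ΣD_r`) is used — conservative when fed per-contig means,
since means understate the underlying base counts.  The headline number is
reported raw and rounded to the nearest 5%, the resolution at which such
abundances are conventionally quoted.

## ORF screen

Six-frame calling: ATG→stop, standard code, peptide ≥ 70 aa (the floor
chosen because known short CMS peptides run to 79 aa), frames wrapping the
origin on circular molecules, the longest ORF per stop per frame, ORFs
containing N skipped and counted.  Start codons are configurable;
`require_start=False` counts stop-free open frames instead — the
genome-browser-style tally used for the raw "predicted orfs" number, which
is several-fold larger than the ATG-initiated count on the same sequence.
ORFs with identical nucleotide sequence are reported once (the screen
counts distinct orfs), with subgenome records taking precedence.

Classification: an ORF is *common* iff it aligns, on either strand, over
≥ 99% of its length at > 99% identity to the reference (full-query infix
alignment via edlib's k-limited bit-parallel algorithm; reference records
concatenated with N runs no near-identity alignment can cross).  All other
ORFs are *specific*.  Identity is nucleotide-level.  Reference records are
written with a 3-kb circular-junction pad (start repeated after the end) so
origin-spanning ORFs remain alignable; annotation coordinates stay within
the unpadded length.

Chimera detection: each specific ORF is compared with every annotated gene
sequence by the same anchored exact-run chaining used for shared repeats;
a hit of ≥ 30 bp at ≥ 0.9 identity covering less than the whole ORF marks
it chimeric (a full-length match would make it a gene copy, not a chimera).

Transmembrane segments use the Kyte–Doolittle hydropathy scale with a
19-residue window, threshold mean > 1.6, overlapping windows merged, each
reported segment ≥ 19 aa.  This is a transparent stand-in for an HMM
topology predictor and is labelled `hydropathy-TM` in all outputs; random
peptides occasionally exceed the threshold, so the flag ranks candidates
rather than asserting topology.

Known-gene placement locates every annotated gene/exon on the resolved
molecules under the same alignment contract and flags genes whose exons
fall on different subgenomes — the trans-splicing split that forces joint
transmission of both subgenomes.

## In-silico validation

Virtual PCR reports every convergent forward/reverse site pair within the
product ceiling, on both strands and across the origin; matching is exact
by default, IUPAC degeneracy is expanded, and any allowed mismatches are
excluded from the three 3′-terminal bases (extension requires 3′
complementarity).  Virtual digestion cuts at every recognition-site
occurrence on either strand (palindromes once), with cut positions at site
starts (overhang geometry is not modelled); fragments tile the molecule
exactly (circular: n sites → n fragments; none → uncut flag).  A probe
"hybridises" when it aligns full-length at ≥ 95% identity on either strand
of a fragment — a stringency stand-in with no thermodynamics, since blot
stringency is not computable from sequence alone.

## The synthetic generator and the BoroToy fixture

`simulate_genome` realises configured circles (ordered, oriented segment
walks; repeats are exact copies, as perfect organelle repeats are),
plasmid-like molecules with their own GC targets, shared identical blocks,
restriction-site plants within motif-scrubbed windows, known genes
(single-exon coding or multi-exon) and planted ORFs.  Observation
(`fragment_and_observe`) collapses repeats to one contig each, draws
per-base depths as Poisson with mean `coverage × copy-sum` and link support
as Poisson with mean `bridge_rate × coverage × junction copy-sum`
(zero draws emit no row, as unobserved bridges would).  `make_reference`
copies every truth molecule, overwrites the not-in-reference ORF windows
with fresh random sequence, and annotates the known genes — a matched
reference playing the standard-cultivar role.

Planted-ORF cassettes are engineered so the screen's ground truth is exact:
each cassette is flanked by a 12-bp pad containing stop codons in all six
frames (no outside reading frame runs through), preceded by an in-frame
stop (the called ORF starts at the planted ATG), and peppered — in its
random codon stretches, donor fragments and coding genes alike — with a
five-codon "stop shield" that is sense in the encoded frame but stops all
five other frames at least every ~55 codons, so no chance ORF above the
70-aa floor can arise inside an engineered window in a foreign frame.  A
defensive check enforces this at generation time.

**BoroToy** realises the studied genome architecture at full scale:
MC-1 (95 kb) alone as subgenome-1; MC-2 (142 kb), MC-3 (54 kb), MC-4
(157 kb) and MC-5 (100 kb) interlocking via c0032 (in MC-2/3/4; twice,
inverted, in MC-3) and c0026 (MC-2/4/5) into subgenome-2 (453 kb); MC-3 at
copy number 0.1 carrying the N-atp6-flank contig c0043 (so c0043 and c0031
sequence at ~10% of baseline, c0026 at ~3×, c0032 at ~2.2×); plasmids B1–B4
at their reported lengths and GC contents; a 450-bp identical block at the
c0002/c0003 junction and inside c0015, flanks pinned so the maximal match
is exactly 450 bp; an EcoRI map giving the probe a 1.5-kb fragment on
subgenome-1 and 1.3 kb on the recombinant; 17 planted specific ORFs
(12 chromosomal, 5 plasmid-borne) with the four chimeras cob→orf449,
orf288→orf310, atp4→orf97 and coxI→orf79 (the last with a hydrophobic
stretch); and the trans-spliced nad1/nad5 exon sets split across the two
subgenomes.  Junction primers are 20-mers extracted at fixed offsets in
c0026 and c0006, flanking the preserved c0026→c0032→c0006 connection, with
a 7,300-bp product.  Coverage is 50×, genome-wide GC target 0.44, and the
bridge rate 2.0 spanning pairs per coverage unit — an 8-kb insert library
physically spans a junction far more often than per-base coverage, and at
much lower rates the 0.1-abundance molecule's junctions would drop out of
the evidence entirely.

**What the fixture does not emulate:** read-level errors and base-calling
(depths and links are drawn directly), biased or over-dispersed coverage,
imperfect/nested repeats, real gene sequences (genes are stop-free random
codons), genuine recombination dynamics over generations, and homology to
actual databases.  Passing tests therefore demonstrate the *inference
machinery* — graph construction, parsimony resolution, depth ratios,
screening and validation logic — under the stated noise model, not
robustness to assembler artefacts or biological sequence composition.

## Numerical and procedural choices

* Single seed per run, split deterministically per stage (seed, seed+1,
  seed+2 for genome, observation and reference); identical configuration
  and seed reproduce every artifact byte for byte.
* Rounding is `floor(x + 0.5)` for copy numbers (ties away from zero, not
  banker's); GC is reported to 0.1%.
* Cycle-cover tie-breaks, canonical forms and sorted iteration orders make
  the resolver deterministic under permutation of input rows.
* Plasmid-like classification: single-contig circles shorter than 10 kb
  (configurable), numbered by descending length.
* Pipeline problem sizes: the bundled analyses run the full ~550-kb fixture;
  property suites use 3–6-contig graphs against an exhaustive cycle-cover
  oracle, 5-kb sequences against a position-by-position six-frame oracle,
  and 20-seed replicate sets for recovery statistics.

## Known limitations

* Undirected end-pair links cannot phase perfect inverted-repeat isomers;
  the order-alternative report says so (tie flag) instead of guessing.
  Resolving such isomers needs oriented long-range evidence.
* The merged subgenome sequence is one representative of an isomer family;
  which three-contig contexts it shows depends on the (deterministic)
  insertion order.  All pairwise junctions are always present.
* The parsimony objective can be degenerate (several covers of equal
  length); the subdivision-preferring tie-break picks one reproducibly but
  the alternatives are real, as the underlying biology suggests.
* `estimate_abundance` on per-contig means uses a conservative interval;
  per-base depths give the calibrated bootstrap.
* The hydropathy rule is not a topology predictor; chimera detection is
  limited to near-identical donors (≥ 0.9 identity), not remote homology.
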
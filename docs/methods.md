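# Methods

`viroseek` re-implements, at desk scale and fully seeded, the computation a
viral-metagenomics study performs between raw sequencer output and a virome
report: preprocessing, host/bacterial subtraction, ensemble de novo assembly,
translated homology classification with virus/nonvirus arbitration,
hallmark-motif annotation with an ICTV-style species-demarcation rule, and
distance-based comparison. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Synthetic communities

Real discovery samples are dominated by host and bacterial DNA with viruses
present at trace abundance. The generator reproduces that regime: a default
community of one host genome (200 kb), one bacterial genome (100 kb), a
linear ~4.6 kb genome with the NS1/VP1 organisation of parvoviruses and a
circular 4.8 kb genome with the VP2/VP1/ST/LT organisation of polyomaviruses,
the two viral genomes held at 30× fold-coverage within a 50,000-pair pool of
2 × 250 bp reads. Viral ORFs are built by reverse-translating random peptides
(uniform codon choice, no stop codons) around verbatim hallmark-motif
instances — Walker A `GPASTGKS`, Walker B `VIWIEE`, the rolling-circle
motifs `TKLHTHLILG` and `VLTYTHKQT`, the PLA2 `HD`/`D` residues and `YLGPG`
calcium loop in VP1, and `HPDKGG`, an LxCxE instance, `GPINSGKT` and the
`CKDC`/`CLVC`/`CFSC` zinc clusters in LT — so the annotation stage can be
validated against construction. An in-frame stop is planted immediately
upstream of each ORF so the first ATG is the true start and truth peptides
are exact. Circular genomes are stored as linear strings with a topology
flag; reads and ORFs wrapping the origin use modular coordinates.

Read artefacts emulated: PCR duplicates (a configurable fraction of pairs,
default 10%, re-emitted byte-identically so the positional dedup key is
exercised exactly); linear quality decay from Q37 toward a floor of Q15 with
Gaussian jitter (σ = 2), which yields the sub-Q20 3′ tails the trimmer must
remove; substitution noise at 0.2% per base, independent of the quality
track; and adaptor run-through (Nextera transposase sequence) whenever the
insert (normal, mean 350 sd 60) is shorter than the read. Not modelled:
platform-specific error spectra, indel errors, optical duplicates, GC bias
and coverage unevenness beyond multinomial sampling. Passing tests therefore
demonstrate correctness of the stage contracts on a clean but adversarial
caricature of the data, not performance on real libraries — in particular
the subtraction stage faces synthetic references that are exact, whereas real
host references are incomplete.

## Preprocessing

Duplicates are keyed on 1-based positions 5–55 of each read (reads shorter
than the key interval are keyed on their full sequence; N matches only N).
One copy per key group survives — by default the first seen, for
reproducibility independent of RNG state; a seeded random-survivor mode is
available. In the pipeline the key is taken from R1 and the mate is dropped
with it; whether the original workflow keyed single ends or concatenated
pairs is not decidable, so both the key interval and the pairing behaviour
are configurable.

Quality trimming removes the contiguous 3′ tail of bases below Phred 20,
stopping at the first base at or above threshold (internal low-quality bases
are retained). Adaptor clipping is a deliberately simple suffix rule: the
read is clipped at the earliest position where either a full adaptor occurs
with at most one mismatch, or an adaptor prefix of at least 8 exact bases
runs to the read end. This replaces a BLAST-based vector screen; synthetic
adaptors are known exactly, so alignment-scored screening adds nothing here.
Reads shorter than 50 bases after trimming are discarded.

Subtraction implements the contract an aligner-based filter enforces: a read
is background iff it has an ungapped alignment of ≥ 60 consecutive bases to
a reference (either strand) with ≤ 2 mismatches. The implementation is exact
20-mer seeding followed by mismatch counting along the seed diagonal. With
≤ 2 mismatches per 60-base window a window always contains an exact 20-mer
(60/(2+1) = 20), so seed-and-extend is equivalent to the exhaustive
sliding-window check — asserted against that oracle on 500 reads. N bases
count as mismatches, which errs toward retaining ambiguous reads.

## Ensemble assembly

Reads are split into `n_partitions` (default 4) random seeded groups; each
group is assembled at every k in {21, 31, 41} as strand-canonical de Bruijn
unitigs (k-mers below count 2 dropped; at a branch the walk continues only
onto a successor whose count dominates every alternative 3:1, which resolves
error tips and bubbles in favour of coverage). Coverage gaps and branch
breakpoints land at different places in different partitions and k values,
so the pooled fragments tile the genome even where any single sub-assembly
fragments; a greedy longest-overlap-first overlap-layout-consensus pass
(suffix/prefix overlap ≥ 35 bases at ≥ 98% identity, both strands,
containment removal, overlap columns taken from the longer fragment on ties)
merges them. The specific k values, count threshold, partition count and OLC
thresholds are not dictated by any published description — they were chosen
once for 250 bp reads and few-kilobase genomes and are all configurable.

A circular template assembles into a linear string whose ends repeat (a
k−1-mer for a pure unitig cycle, longer after OLC extension). If a contig's
prefix equals its suffix over ≥ 20 bases the repeat is collapsed once and
the contig flagged circular; homopolymers are flagged ambiguous instead of
circularised. On the default community this yields the circular genome at
exactly its true 4,800 bases.

Partitioning is random; whether the original ensemble partitioned randomly
or binned reads by reference is unknown, and random partitioning is the
neutral interpretation.

## Classification

Contigs and unassembled reads are translated in all six frames and searched
against a labelled protein database by exact 4-mer word seeding and ungapped
bidirectional X-drop extension (X = 15 matrix units) under BLOSUM62; stop
codons terminate extension. Significance is the ungapped Karlin–Altschul
statistic E = K·m·n·e^(−λS) with λ = 0.3176, K = 0.134, m the translated
query length and n the database residue count. Two deliberate
simplifications: no edge-effect length correction (search spaces here are
tiny, so the correction is negligible against the decades-wide margins of
the thresholds), and no gapped extension stage (the contract being
reproduced is the threshold logic, and ungapped scoring is the simplest
sound statistic for it). No low-complexity masking is performed; synthetic
sequences are complexity-controlled.

A query is a candidate iff its best hit against the viral database has
E < 0.01. Candidates are re-searched against the combined virus + nonvirus
database; hits with E < 10 are ranked by E-value, then raw score, residual
ties resolved toward nonvirus (the conservative direction for a filter whose
purpose is suppressing false viral calls), then record id — and the
candidate is kept only if the top hit is labelled virus. A taxon is flagged
as a mammalian-virus detection when its best E-value is below 10⁻¹⁰. The
E-ceiling of 10 for the arbitration ranking is a documented choice; only the
ranking rule itself is externally constrained.

## Annotation

The motif grammar compiles degenerate notation left-to-right: `x` any
residue, `u` uncharged, `-` any-or-none, uppercase letters exact, `T/S`
alternation at one position, uppercase `X` any. Uncharged means the 20
standard residues minus D, E, K, R and H — histidine is treated as charged,
a choice under which every planted hallmark instance validates. The scanner
reports every matching window at every offset, trying optional positions
both ways. Notable consequence of the grammar: the 9-mer `TKLHTHLIL` cannot
align its histidines to `xuHuHuuux` (its K is charged at a `u` position),
but with one residue of context (`TKLHTHLILG`) the window one position in
matches — the scanner is asserted on exactly this behaviour. The
`CXXC-CLVC and CFSC` zinc-cluster notation is read as three independent
patterns (`CXXC`, `CLVC`, `CFSC`); a spaced-composite reading is possible
but not the default.

ORFs are ATG-initiated, stop-terminated, ≥ 100 codons by default, on both
strands. Circular genomes are scanned as a tripled string: an ORF is
accepted only after an in-frame stop has been seen (true upstream context)
and only when its start falls in the middle copy — this reports each
circular ORF exactly once and makes the ORF set invariant under rotation.

Hallmark panels: NS1 = {Walker A, Walker B, RCR-1, RCR-2}; VP1 = {PLA2 HD,
a catalytic D 20–60 residues downstream of an HD hit (typical spacing; the
exact gap is configurable), YLGPG}, evaluated only in the N-terminal third
of the ORF; LT = {HPDKGG, LXCXE, Walker A, CXXC, CLVC, CFSC}. A verdict
("consistent with …") is issued when a panel is fully satisfied by a single
ORF. Degenerate panels have limited specificity — a long random protein can
satisfy the loosest panel by chance — so verdicts confirm a homology-based
identification rather than replace it.

Species demarcation follows the ICTV-style rule for parvoviruses: a genome
is a new-species candidate iff its NS1 is strictly below 85% identity to
every reference NS1 (global affine alignment by default; the aligner is
injectable).

## Comparison

`align_pair` is Gotoh's three-matrix affine dynamic programme (BLOSUM62,
gap open 11, extend 1; a gap of length L costs open + extend·L) with
deterministic traceback (diagonal over up over left on ties). Percent
identity is identical columns over aligned columns, gap columns excluded;
local mode is the headline figure (approximating hit-region identities),
global mode serves demarcation. Neighbor joining is the Saitou–Nei
algorithm with the standard Q criterion, label-order tie-breaking, and
negative branch lengths clamped to zero with the deficit shifted to the
sibling. Exactly additive matrices are reproduced to path-length precision;
maximum-likelihood tree inference and multiple alignment are out of scope.

## Numerical and degenerate-input choices

E-value exponentials underflow to zero harmlessly (ties then break on raw
score); the exponent is clamped to avoid overflow for strongly negative
scores. Empty read sets, empty proteins, reads shorter than the dedup key or
the subtraction window, all-optional motif patterns, homopolymer contigs and
two-taxon distance matrices all have defined behaviour (tested). All
randomness flows from explicit integer seeds; re-running any stage with the
same inputs and seed is byte-identical.

## Problem sizes

The default end-to-end configuration — 50,000 pairs over a 300 kb background
and two viral genomes — was chosen so the full pipeline, the test suite and
the acceptance script each complete in minutes on a single CPU while leaving
every stage non-trivially exercised (tens of thousands of background reads
to subtract, ~900 viral reads to assemble). Unit and property tests use
smaller instances sized to their oracle (e.g. exhaustive alignment
enumeration at ≤ 7 residues, exhaustive subtraction windows at 4–5 kb
references).

## Known limitations

No gapped alignment in the translated search; no mate-pair scaffolding or
error correction in assembly; no splice-aware gene models (spliced VP1/LT
isoforms are not reconstructed); subtraction assumes mismatch-only
divergence from references (no gapped mapping); the NJ tree is a distance
summary, not a substitution-model phylogeny. The synthetic generator's
simplifications mean quantitative results (e.g. 100% background removal)
are upper bounds relative to real data.
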
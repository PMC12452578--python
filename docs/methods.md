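# Methods

This note documents the models, parameter choices and known limitations
behind `mabseq`.  It is the package's own account of its science; every
number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Consensus building and clustering

Sanger reads of plasmid clones derived from one transcript differ only
by sequencing error, while a second transcript — typically the
non-functional κ chain retained by myeloma fusion partners — diverges
far beyond it.  Reads are clustered by **single linkage on pairwise
global-alignment identity** (match +1, mismatch −1, gap open −2, gap
extend −1; identity = identical columns / alignment columns).  The
default threshold is **0.99**: clone reads at the sub-percent error
level typical of plasmid Sanger sequencing stay together, while a
different transcript (tens of percent divergence) always splits.  A
single-nucleotide difference alone cannot separate two ~550-nt
sequences at any usable threshold (identity ≈ 0.998); separation works
because the aberrant transcript is a *different rearrangement*, not a
point variant of the productive one.

Consensus is a column-wise majority vote over pairwise alignments to
the longest cluster member (full MSA machinery is unnecessary for
near-identical reads).  Exact ties emit the IUPAC code of the tied
bases; columns with a strict gap majority are deleted; `N` (base-caller
ambiguity) never wins a vote.  Insertions relative to the backbone are
kept only with strict majority support.

## Productive/aberrant QC

The ORF is anchored at an ATG within the first 90 nt (the natural
secretion-leader start survives in 5'RACE amplicons); among candidate
starts the longest stop-free stretch wins.  A stop is **premature**
when it occurs before 90 % of the expected chain length (consensus 3'
end by default) — junction-frameshift chains truncate far upstream, so
the margin is generous.  A transcript is flagged aberrant when its
global identity to any known non-functional reference reaches **0.95**
or its ORF carries a premature stop; the flag is monotone in the
identity threshold by construction.

## CDR3 and germline assignment

CDR3 is the codons strictly between the conserved second cysteine of
FR3 and the J anchor (Trp for heavy, Phe/Trp for light), located by
**anchor projection**: the best-scoring germline V and J references are
infix-aligned into the consensus and their anchor positions (last
in-frame Cys codon of V; first [F/W]-G-x-G motif of J) are mapped
through the alignment.  Motif regexes on the query itself would fail on
somatically mutated frameworks; the projection reuses alignments the
germline assignment computes anyway.

Germline identity is plain global-alignment percent identity over the
aligned reference span.  This is deliberately simpler than IgBLAST's
composite scoring, so values are comparable but not bit-identical to an
IgBLAST report; they are treated as descriptive.  References within
0.1 percentage points of the best are reported as co-best calls, which
reproduces the common situation of indistinguishable alleles.  Both
strands are scored and the better orientation kept, since plasmid
sequencing returns either strand.

## Isotyping and primer audit

The five mouse IgG CH1 references are mined for **minimal unique
windows** (k = 8–20 nt): windows occurring in exactly one subclass
reference (either strand), with windows containing a shorter unique
window suppressed.  Subclass calling is an exact-match scan of these
motifs on both strands of the consensus; a subclass is called only with
exclusive support, otherwise "ambiguous".  Exact matching is justified
because the motifs sit in highly conserved sequence and the query is a
consensus, not a raw read.  Light-chain class is the best
constant-region identity above 0.90, computed as **overlap identity**
(free end gaps on both sides, minimum 60 overlapping columns) because
the amplicon contains only a stub of the constant exon.

The primer audit slides each primer (or its reverse complement,
antisense preferred for RT/PCR primers) ungapped across each reference
and reports the minimum-Hamming placement.  Ungapped is the right model
for annealing: an indel inside a primer site aborts amplification
anyway.

## Primer design and amplicon prediction

The CDR3-anchored forward primer keeps its 5' end pinned to the CDR3
start — the junction is what makes it clone-specific — and only the 3'
end is trimmed or extended (length 15–40 nt) to reach the Tm window,
default **55–65 °C** by nearest-neighbour thermodynamics (biopython
`Tm_NN`, 50 mM Na⁺, 250 nM primer / 25 nM complement).  The primer must
occur exactly once in the template.  The predicted RT-3'RACE product
runs from the forward site to the 5' end of the poly-A tract (first run
of ≥10 A within the final 50 nt) plus the full oligo-dT anchor-primer
length, which forms the amplicon's 3' terminus.

## Peptide mass fingerprinting

Two cleavage chemistries are modelled.  **Trypsin**: after Lys/Arg
unless Pro follows; default missed-cleavage budget 2.  **Dilute
sulfuric acid**: Asp-selective hydrolysis cleaving on *both* sides of
aspartate (Asp-X and X-Asp bonds); acid hydrolysis is intrinsically
partial, so the default budget is 5 missed sites.  Fragments are
filtered to 4–40 residues (reflector mass window, matrix-region
exclusion).  Masses are monoisotopic [M+H]⁺ (residue masses + water
18.010565 + proton 1.007276, via pyteomics); cysteine is unmodified by
default because the protocol omits alkylation, with carbamidomethyl
available as a fixed modification.

Peak matching assigns each measured peak to the theoretical peptide
with the smallest |ppm error| within the tolerance (default **100 ppm**,
appropriate for externally calibrated reflector MALDI; configurable in
ppm).  Coverage is the residue-union of matched peptides over the
concatenated mature chains.  A CDR counts as **assigned** only when one
matched peptide fully contains its span — partial overlap is not
protein-level verification of the junction.  CDR1/CDR2 spans are
user-supplied (protein-level inputs); CDR3 spans derive from the DNA
annotation.

## Synthetic study conditions

The fixture generator emulates the workflow's study conditions with
full ground truth: 8 clone reads per chain at a per-base substitution
error of 0.001 (plasmid Sanger reads are nearly error-free); a κ read
set in which 50 % of clones derive from an aberrant fusion-partner
transcript — a *different* germline V rearrangement (IGKV12-41-style)
whose V–J junction carries a 1-nt deletion that reads into a stop codon
nine codons downstream; full mRNA architectures (5'UTR, leader,
V-(D-)J, constant exons, 3'UTR, 30-nt poly-A) sized so the predicted
constant-region amplicons are 1300 bp (heavy) and 600 bp (κ); five CH1
references identical except at engineered discriminative columns, with
primer-site substitutions planted so the heavy RT primer shows 0/0/0/0/5
mismatches across IgG1/2a/2b/2c/3 and the PCR primer 0/0/1/0/4; strain
constant regions differing by a TG↔GT dinucleotide swap in CH3 that
exchanges valine (C57BL/6J) for glycine (NOD) at mature-chain position
435; and MALDI peak lists with configurable dropout, Gaussian m/z
jitter (15 ppm default) and uniform decoy peaks.

Two numerical safeguards make the generator a pure, robust function of
(seed, config).  First, because the subclass motifs are short (down to
8 nt), chance occurrences in the random template parts are likely; the
generator therefore *scrubs* every random region that ends up in a
consensus, removing motif occurrences by single stop-safe substitutions
(mirrored into the paired germline so planted identity percentages are
preserved).  Second, a validation pass re-checks all planted guarantees
(mismatch counts under the minimum-Hamming scan, junction uniqueness,
motif exclusivity per subclass amplicon, variant separability) and
rebuilds with a derived sub-seed in the rare case a junction-spanning
window slips through.

What the fixtures do **not** emulate: chromatogram-level error
structure (no indel errors, no quality scores), real germline database
diversity (a handful of mini-references, not IMGT), homology between
subclass CH1 exons beyond a shared random backbone, realistic MALDI
intensity models, and isotope envelopes.  Passing tests therefore
demonstrate the correctness of the algorithms under controlled
conditions, not recall against real repertoires or instruments.

## Numbering and other conventions

Amino-acid positions are **linear 1-based in the mature (leaderless)
chain**; the strain-difference position 435 is stated under this
convention (EU numbering is not implemented, and the offset between
sample coordinates and mature numbering is an explicit parameter).
Nucleotide spans are half-open 0-based internally and 1-based inclusive
in reports.  Clusters are ordered by size then smallest member id, so
all outputs are invariant to read input order.  Melting-temperature
constants, identity thresholds, ppm tolerance and missed-cleavage
budgets are single documented defaults, overridable per call and via
the workflow config.

## Limitations

* Germline identity is not IgBLAST-equivalent; do not compare absolute
  percentages across tools.
* The leader/mature boundary is a caller-supplied length, not a signal
  peptide prediction.
* Acid-hydrolysis specificity is modelled as strictly Asp-directed;
  minor non-specific cleavage observed in real spectra is not emulated.
* λ light chains are handled by the same machinery but with a
  low-confidence flag when primer mismatches suggest inefficient
  amplification; no λ fixture read sets are generated by default.
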
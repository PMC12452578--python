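# mabseq

Computational layer for a two-step Sanger workflow that recovers the
**full-length sequence of a monoclonal antibody from hybridoma cells** —
for labs that sequence a handful of clones in-house rather than shipping
cells to an RNA-seq service.

Step 1 amplifies the variable regions (5'RACE-SMART), clones them, and
Sanger-sequences ~8 plasmids per chain.  Step 2 uses the clone-specific
CDR3 junction as a forward primer to amplify the constant regions by
RT-3'RACE, and verifies the CDRs at the protein level by MALDI-TOF
peptide mass fingerprinting.  `mabseq` covers everything computational
in between:

* **consensus** — single-linkage clustering of clone reads on pairwise
  global-alignment identity (default threshold 0.99) and column-wise
  majority-vote consensus (ties → IUPAC codes, gap-majority columns
  deleted, `N` never wins).
* **chain_qc** — ORF analysis flags non-productive transcripts
  (premature stop after a V–J junction frameshift, the classic myeloma
  fusion-partner artefact) and matches against known non-functional κ
  references; codon-aligned constant-region comparison ranks mouse
  strain references (C57BL/6J vs NOD).
* **vdj_annotation** — CDR3 located IMGT-style between the conserved
  FR3 cysteine and the J-segment [F/W]-G-x-G anchor, by projecting the
  anchors of the best-matching germline V and J references through the
  alignment; germline calls are plain percent identity with co-best
  ties reported together.
* **isotyping** — mouse IgG subclass (IgG1/2a/2b/2c/3) called at the
  DNA level from subclass-unique CH1 motifs that ride along with the
  variable-region amplicon; ungapped minimum-Hamming audit of primer
  binding sites.
* **primer_design** — CDR3-anchored forward primer (5' end pinned to
  the junction, 3' end trimmed/extended for a 55–65 °C nearest-neighbour
  Tm window) and in-silico RT-3'RACE amplicon prediction.
* **ms_fingerprint** — in-silico trypsin (after K/R, not before P) and
  dilute-sulfuric-acid (both sides of Asp, partial) digestion,
  monoisotopic [M+H]⁺ masses, ppm-tolerance peak matching, sequence
  coverage and per-CDR verdicts (a CDR is verified only when one
  matched peptide fully contains it).
* **synthetic_fixtures** — a generator that builds every input with
  known ground truth: germline mini-references, full mRNA architectures
  (leader + V-(D-)J + constant exons + 3'UTR + poly-A), clone reads
  with a planted aberrant κ variant, CH1 references with planted
  primer-site mismatches, and simulated MALDI peak lists.

## Worked example

```python
from mabseq.chain_qc import annotate_orf, flag_aberrant
from mabseq.consensus import cluster_reads
from mabseq.fixtures import FixtureConfig, build_world, make_clone_reads
from mabseq.vdj import annotate_chain

world = build_world(FixtureConfig(seed=1))       # synthetic study conditions
reads, truth = make_clone_reads(world, "kappa")  # 8 Sanger clone reads

for cluster in cluster_reads(reads, identity_threshold=0.99):
    call = flag_aberrant(cluster.consensus, world.references["aberrant_kappa"])
    print(cluster.member_ids, "ABERRANT" if call.flagged else "productive")
    if not call.flagged:
        ann = annotate_chain(cluster.consensus, "kappa",
                             world.references["germline_V_kappa"],
                             world.references["germline_J_kappa"])
        print(ann.v_call, f"{ann.total_identity_pct:.1f}%", ann.cdr3_aa)
```

prints

```
['K01', 'K03', 'K04', 'K06'] productive
IGKV4-61*01 99.2% QQYHSYPRT
['K02', 'K05', 'K07', 'K08'] ABERRANT
```

Two κ transcripts were cloned: the productive chain (germline
IGKV4-61*01 at 99.2 % identity, junction peptide QQYHSYPRT) and, in 50 %
of the clones, a non-functional fusion-partner transcript whose 1-nt
V–J junction deletion truncates the ORF — exactly what the QC stage is
there to catch.  The `examples/` directory walks through the other
capabilities one script at a time (isotyping and primer audit, primer
design and strain disambiguation, fingerprint verification); each
prints the numbers it computes and says what they mean.

There is also a thin CLI mirroring the workflow
(`mabseq fixtures | consensus | qc | annotate | isotype | scan-primers |
design | fingerprint | run-step1 | run-step2`); exit codes are 0
success, 2 usage, 3 validation, 4 QC failure.

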
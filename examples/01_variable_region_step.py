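"""Variable-region step: clone reads -> clusters -> QC -> V(D)J annotation.

Builds the packaged synthetic read sets (eight clones per chain, half of
the kappa clones carrying the aberrant fusion-partner transcript), then
runs the analysis a lab would run on Sanger reads of cloned RT-PCR
amplicons.
"""

from mabseq.chain_qc import annotate_orf, flag_aberrant
from mabseq.consensus import cluster_reads
from mabseq.fixtures import FixtureConfig, build_world, make_clone_reads
from mabseq.vdj import annotate_chain

world = build_world(FixtureConfig(seed=1))
reads, truth = make_clone_reads(world, "kappa")

clusters = cluster_reads(reads, identity_threshold=0.99)
print(f"{len(reads)} kappa clone reads -> {len(clusters)} cluster(s)")

for i, cluster in enumerate(clusters, 1):
    orf = annotate_orf(cluster.consensus)
    call = flag_aberrant(cluster.consensus, world.references["aberrant_kappa"], orf=orf)
    status = "ABERRANT" if call.flagged else "productive"
    print(f"  cluster {i}: {cluster.size} reads {cluster.member_ids} -> {status}"
          f" (reason: {call.reason}, stop at aa {orf.stop_position_aa})")
    if not call.flagged:
        ann = annotate_chain(cluster.consensus, "kappa",
                             world.references["germline_V_kappa"],
                             world.references["germline_J_kappa"])
        print(f"    V call: {ann.v_call}  J call: {ann.j_call}"
              f"  identity {ann.total_identity_pct:.1f}%")
        print(f"    CDR3: {ann.cdr3_nt} -> {ann.cdr3_aa}")

flagged = sum(c.size for c in clusters
              if flag_aberrant(c.consensus, world.references["aberrant_kappa"]).flagged)
print(f"non-functional kappa clones: {100 * flagged / len(reads):.0f}%")
# The aberrant transcript carries a 1-nt V-J junction deletion whose frameshift
# hits a premature stop; half the clones derive from it, as is typical for
# myeloma fusion partners, and QC removes them before any downstream step.
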
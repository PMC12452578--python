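"""Orchestration of the two-step sequencing workflow.

Step 1 (variable regions): cluster clone reads per chain, call a
consensus per cluster, run productive/aberrant QC, annotate the V-(D-)J
junction and germline calls, call the IgG subclass and light-chain
class at the DNA level, and design the CDR3-anchored forward primer for
step 2.  A failure in one chain never aborts the others.

Step 2 (constant regions + protein verification): consensus of the
constant-region clones, strain comparison of the heavy constant region,
assembly of the full-length chain (leader + V-(D-)J + constant),
translation, and peptide-mass-fingerprint verification of the CDRs.

The assembled :class:`WorkflowReport` serialises to one JSON document
(schema shipped as ``docs/report.schema.json``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any

from Bio.Seq import Seq

from . import __version__
from .chain_qc import annotate_orf, compare_to_strain, flag_aberrant
from .consensus import cluster_reads
from .errors import MabseqError, QcFailure
from .fingerprint import CdrSpan, digest, match_peaks
from .io import NucleotideRead, PeakList, PrimerRecord, ReferenceRecord
from .isotyping import call_isotype, derive_motifs
from .primer_design import design_cdr3_primer, predict_amplicon
from .vdj import annotate_chain

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "identity_threshold": 0.99,
    "aberrant_min_identity": 0.95,
    "tm_window": [55.0, 65.0],
    "tol_ppm": 100.0,
    "light_identity_min": 0.90,
}


@dataclass
class ChainResult:
    chain: str
    n_reads: int
    clusters: list[dict] = field(default_factory=list)
    error: str | None = None


@dataclass
class WorkflowReport:
    """Machine-readable result of the two-step workflow."""

    tool_version: str
    config: dict
    chains: dict[str, ChainResult] = field(default_factory=dict)
    isotype: dict | None = None
    primers: dict[str, dict] = field(default_factory=dict)
    strain_comparison: list[dict] = field(default_factory=list)
    assembly: dict = field(default_factory=dict)
    fingerprint: dict | None = None
    notes: list[str] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), default=_jsonable, **kwargs)


def _jsonable(obj: Any):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, tuple)):
        return list(obj)
    return str(obj)


def run_step1(
    reads_by_chain: dict[str, list[NucleotideRead]],
    references: dict[str, list[ReferenceRecord]],
    primers: list[PrimerRecord],
    config: dict | None = None,
) -> WorkflowReport:
    """Variable-region step: consensus -> QC -> annotation -> isotype -> primer design."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    report = WorkflowReport(tool_version=__version__, config=cfg)
    if not reads_by_chain:
        raise MabseqError("no read sets supplied")

    motifs = None
    if references.get("CH1_exon"):
        motifs = derive_motifs(references["CH1_exon"])

    any_ok = False
    for chain, reads in sorted(reads_by_chain.items()):
        result = ChainResult(chain=chain, n_reads=len(reads))
        report.chains[chain] = result
        try:
            clusters = cluster_reads(reads, cfg["identity_threshold"])
            log.info("step1/%s: %d cluster(s) from %d reads", chain, len(clusters), len(reads))
            for cluster in clusters:
                entry = _process_cluster(chain, cluster, references, primers, cfg, motifs, report)
                result.clusters.append(entry)
            if any(not c["aberrant"] for c in result.clusters):
                any_ok = True
        except MabseqError as exc:
            log.warning("step1/%s failed: %s", chain, exc)
            result.error = str(exc)
    for chain in ("lambda",):
        if chain not in reads_by_chain:
            report.notes.append("no lambda amplicon")
    if not any_ok:
        raise QcFailure("all chains failed QC")
    return report


def _process_cluster(chain, cluster, references, primers, cfg, motifs, report) -> dict:
    orf = annotate_orf(cluster.consensus)
    entry = {
        "consensus": cluster.consensus,
        "members": cluster.member_ids,
        "size": cluster.size,
        "orf": dataclasses.asdict(orf),
        "aberrant": False,
    }
    aberrant_refs = references.get("aberrant_kappa", [])
    if aberrant_refs and chain != "heavy":
        call = flag_aberrant(cluster.consensus, aberrant_refs, cfg["aberrant_min_identity"], orf=orf)
        entry["aberrant"] = call.flagged
        entry["aberrance"] = {"reason": call.reason, "best_ref": call.best_ref_id,
                              "best_identity": call.best_identity}
    else:
        entry["aberrant"] = orf.premature_stop

    v_key = "germline_V_heavy" if chain == "heavy" else f"germline_V_{chain}"
    j_key = "germline_J_heavy" if chain == "heavy" else f"germline_J_{chain}"
    try:
        annotation = annotate_chain(
            cluster.consensus, chain,
            references[v_key], references[j_key],
            references.get("germline_D") if chain == "heavy" else None,
        )
        entry["annotation"] = dataclasses.asdict(annotation)
    except (MabseqError, KeyError) as exc:
        entry["annotation_error"] = str(exc)
        annotation = None

    if motifs is not None:
        iso = call_isotype(cluster.consensus, motifs, references.get("constant_light", []),
                           cfg["light_identity_min"], primers)
        entry["isotype"] = dataclasses.asdict(iso)
        if chain == "heavy" and not entry["aberrant"]:
            report.isotype = entry["isotype"]

    if annotation is not None and not entry["aberrant"]:
        try:
            spec = design_cdr3_primer(annotation, cluster.consensus,
                                      tm_window=tuple(cfg["tm_window"]),
                                      name=f"{chain}_cdr3_fwd")
            entry["cdr3_primer"] = dataclasses.asdict(spec)
            report.primers[chain] = entry["cdr3_primer"]
        except MabseqError as exc:
            entry["primer_error"] = str(exc)
    return entry


def run_step2(
    step1: WorkflowReport,
    constant_reads: dict[str, list[NucleotideRead]],
    strain_refs: list[ReferenceRecord],
    peaklists: dict[str, PeakList] | None = None,
    templates: dict[str, str] | None = None,
    anchor_primer: PrimerRecord | None = None,
    cdr12_spans: dict[str, dict[str, tuple[int, int]]] | None = None,
    config: dict | None = None,
) -> WorkflowReport:
    """Constant-region step: consensus, strain ranking, assembly, fingerprint."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    report = step1
    report.config.update(cfg)

    productive = {}
    for chain, result in report.chains.items():
        for cluster in result.clusters:
            if not cluster["aberrant"] and "annotation" in cluster:
                productive[chain] = cluster
                break
    if not productive:
        raise MabseqError("step1 report contains no productive CDR3 annotations")

    # constant-region consensus per chain
    constants = {}
    for chain, reads in sorted(constant_reads.items()):
        clusters = cluster_reads(reads, cfg["identity_threshold"])
        constants[chain] = clusters[0].consensus
        log.info("step2/%s: constant consensus %d nt", chain, len(constants[chain]))

    # in-silico amplicon check against the mRNA templates
    if templates and anchor_primer:
        for chain, template in templates.items():
            if chain in report.primers:
                from .primer_design import PrimerSpec
                spec = PrimerSpec(**report.primers[chain])
                amp = predict_amplicon(spec, template, anchor_primer)
                report.assembly.setdefault("amplicons", {})[chain] = {
                    "product_length_nt": amp.product_length_nt,
                    "covers": amp.covers,
                }

    # strain disambiguation on the heavy constant region, positions reported
    # in linear mature-chain numbering (offset = variable-domain length)
    if "heavy" in constants and strain_refs:
        from .align import align_infix, project_position

        offset = int(cfg.get("vh_aa_len") or 0)
        # the constant amplicon begins at the CDR3 primer; trim to the start
        # of the constant region so positions line up with mature numbering
        aln = align_infix(constants["heavy"], strain_refs[0].sequence)
        const_start = project_position(aln, 0)
        comparisons = compare_to_strain(constants["heavy"][const_start:],
                                        strain_refs, aa_offset=offset)
        report.strain_comparison = [dataclasses.asdict(c) for c in comparisons]

    # full-length assembly and translation
    proteins = {}
    for chain, cluster in productive.items():
        if chain not in constants:
            continue
        orf = cluster["orf"]
        consensus = cluster["consensus"]
        span = cluster["annotation"]["cdr3_span"]
        variable_nt = consensus[orf["start_nt"]:]  # leader + V-(D-)J + CH1 stub
        assembled = _assemble(variable_nt, constants[chain])
        protein = str(Seq(assembled[: len(assembled) - len(assembled) % 3]).translate())
        protein = protein.split("*")[0]
        proteins[chain] = protein
        report.assembly.setdefault("chains", {})[chain] = {
            "nt_length": len(assembled),
            "protein_length": len(protein),
            "internal_stop": "*" in protein,
        }

    # peptide-mass-fingerprint verification
    if peaklists and proteins:
        leader_aa = cfg.get("leader_aa_len") or {}
        report.fingerprint = _fingerprint(proteins, productive, peaklists,
                                          cdr12_spans, leader_aa, cfg)
    return report


def _assemble(variable_nt: str, constant_nt: str) -> str:
    """Splice the variable amplicon onto the constant consensus at their overlap."""
    # find the longest suffix of the constant start inside the variable stub
    for k in range(min(len(variable_nt), len(constant_nt)), 19, -1):
        idx = variable_nt.find(constant_nt[:k])
        if idx >= 0:
            return variable_nt[:idx] + constant_nt
    return variable_nt + constant_nt


def _fingerprint(proteins, productive, peaklists, cdr12_spans, leader_aa, cfg) -> dict:
    from .fingerprint import cdr_spans as make_spans

    chain_map = {"heavy": "heavy", "kappa": "light", "lambda": "light"}
    spans: list[CdrSpan] = []
    theoreticals = []
    chain_lengths = {}
    mature = {}
    for chain, protein in proteins.items():
        label = chain_map.get(chain, chain)
        ann = productive[chain]["annotation"]
        cdr3_aa = ann["cdr3_aa"]
        # mature chain = leader peptide removed; the leader length comes from
        # the caller (CDR1/2 spans are supplied in mature numbering too)
        mature_protein = protein[int(leader_aa.get(chain, 0)):]
        mature[label] = mature_protein
        chain_lengths[label] = len(mature_protein)
        user = (cdr12_spans or {}).get(chain, {})
        spans.extend(
            make_spans(label, mature_protein, cdr3_aa,
                       cdr1=user.get("CDR1"), cdr2=user.get("CDR2"),
                       prefix="H" if label == "heavy" else "L")
        )
        for mode in ("trypsin", "acid"):
            theoreticals.extend(digest(mature_protein, mode, chain=label))

    all_matches = []
    assignments = {}
    coverage_union: dict[str, set] = {}
    for mode, peaks in peaklists.items():
        subset = [t for t in theoreticals if t.cleavage_mode == mode]
        result = match_peaks(peaks, subset, cfg["tol_ppm"], cdr_spans=spans,
                             chain_lengths=chain_lengths)
        all_matches.extend(result.matches)
        for label, (ok, peps) in result.cdr_assignments.items():
            prev = assignments.get(label, (False, []))
            assignments[label] = (prev[0] or ok, prev[1] + [p.sequence for p in peps])
        for m in result.matches:
            coverage_union.setdefault(m.peptide.chain, set()).update(
                range(m.peptide.start, m.peptide.end + 1))
    total = sum(chain_lengths.values())
    coverage = sum(len(v) for v in coverage_union.values()) / total if total else 0.0
    return {
        "n_matches": len(all_matches),
        "coverage_pct": 100.0 * coverage,
        "cdr_assignments": {k: {"assigned": v[0], "peptides": sorted(set(v[1]))}
                            for k, v in sorted(assignments.items())},
        "n_cdr_assigned": sum(1 for v in assignments.values() if v[0]),
        "n_cdr_total": len(assignments),
    }
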
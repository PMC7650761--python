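"""End-to-end virome curation over a (synthetic or real) input bundle.

Wires the modules together: candidate filtering from homology/domain hit
tables, clade/group assignment from the best-bitscore relative, genetic
code selection and interrupted-ORF detection on each candidate contig,
index-hop filtering and tier classification of the count matrix,
exclusion flags, host inference and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from termite_virome import abundance, ecology, orf_codes, taxonomy_host, triage
from termite_virome.io_formats import (
    read_count_matrix,
    read_domain_table,
    read_fasta,
    read_homology_table,
    read_library_metadata,
    read_reference_table,
)


@dataclass
class PipelineResult:
    records: list  # every candidate VirusRecord, flags applied
    final_records: list  # curated virome (no exclusion flags)
    detections: list  # VirusDetection over the filtered matrix
    removals: list  # HopRemoval events
    filtered_counts: pd.DataFrame
    triage_log: list
    unclassifiable: list
    host_predictions: dict  # virus_name -> HostPrediction
    clade_summaries: list
    profiles: list

    @property
    def final_names(self) -> set:
        return {r.virus_name for r in self.final_records}


def load_bundle_dir(bundle_dir) -> dict:
    """Read an on-disk bundle back into the objects the pipeline takes."""
    from pathlib import Path

    d = Path(bundle_dir)
    vc = pd.read_csv(d / "virus_contigs.tsv", sep="\t")
    return {
        "contigs": read_fasta(d / "contigs.fasta"),
        "hits": read_homology_table(d / "homology_hits.tsv"),
        "domains": read_domain_table(d / "domain_hits.tsv"),
        "counts": read_count_matrix(d / "count_matrix.tsv"),
        "meta": read_library_metadata(d / "library_metadata.tsv"),
        "refs": read_reference_table(d / "reference_viruses.tsv"),
        "virus_contigs": vc,
    }


def run_pipeline(
    contigs,
    hits,
    domains,
    counts: pd.DataFrame,
    meta,
    refs,
    virus_contigs: pd.DataFrame,
    thresholds: triage.TriageThresholds = triage.TriageThresholds(),
    contamination_mode: str = "sum",
    hop_threshold: float = abundance.DEFAULT_HOP_THRESHOLD,
) -> PipelineResult:
    seq_of = {c.contig_id: c.sequence for c in contigs}
    meta_by_id = {m.library_id: m for m in meta}
    totals = {m.library_id: m.total_reads for m in meta}
    contig_of_virus = dict(zip(virus_contigs.virus_name, virus_contigs.contig_id))
    virus_of_contig = {v: k for k, v in contig_of_virus.items()}

    # 1. candidate contigs: credible viral hit, no non-viral domain
    retained, log = triage.filter_candidates(
        hits, domains, thresholds, contig_ids=[c.contig_id for c in contigs]
    )

    # 2. index-hop contamination filter on the count matrix
    filtered_counts, removals = abundance.contamination_filter(
        counts, threshold_fraction=hop_threshold, mode=contamination_mode
    )
    lengths = dict(zip(virus_contigs.virus_name, virus_contigs.contig_length))
    detections = abundance.detections_from_matrix(filtered_counts, totals, lengths)
    max_class: dict[str, str] = {}
    order = {"low": 0, "moderate": 1, "high": 2}
    for d in detections:
        cur = max_class.get(d.virus_name)
        if cur is None or order[d.abundance_class] > order[cur]:
            max_class[d.virus_name] = d.abundance_class

    # 3. per-candidate record assembly
    hits_by_contig: dict[str, list] = {}
    for h in hits:
        hits_by_contig.setdefault(h.query_id, []).append(h)
    records = []
    interrupted_by_virus: dict[str, bool] = {}
    for cid in sorted(retained):
        if cid not in virus_of_contig:
            continue  # a contig with no quantified virus row
        vname = virus_of_contig[cid]
        chits = hits_by_contig[cid]
        clade, group, ref = triage.assign_clade_group(chits, refs)
        best_hit = max(chits, key=lambda h: h.bitscore)
        seq = seq_of[cid]
        h_span = (best_hit.align_start, best_hit.align_end)
        code_id, _ = orf_codes.best_code_for_contig(seq, homology_span=h_span)
        orfs = orf_codes.find_orfs(seq, code_id, min_len_codons=30)
        interrupted, _ = orf_codes.detect_interrupted_orf(
            h_span, orfs, coverage_threshold=thresholds.endogenous_orf_coverage
        )
        interrupted_by_virus[vname] = interrupted
        libs = tuple(
            sorted(d.library_id for d in detections if d.virus_name == vname)
        )
        records.append(
            triage.VirusRecord(
                virus_name=vname,
                contig_ids=(cid,),
                library_ids=libs,
                clade=clade,
                group=group,
                genome_length=len(seq),
                closest_relative=ref,
                percent_identity_to_relative=best_hit.percent_identity,
                completeness_ratio=triage.completeness_ratio(
                    len(seq), ref.genome_length
                ),
                code_id=code_id,
            )
        )

    # 4. exclusion flags
    flagged, unclassifiable = triage.apply_exclusions(
        records, interrupted_by_virus, max_class, thresholds
    )
    final = [r for r in flagged if not r.excluded]
    final_names = {r.virus_name for r in final}
    final_dets = [d for d in detections if d.virus_name in final_names]

    # 5. hosts, summaries, profiles
    host_predictions = {
        r.virus_name: taxonomy_host.infer_host(r, final_dets, meta_by_id)
        for r in final
    }
    clade_summaries = taxonomy_host.summarize_clades(
        final, final_dets, host_predictions
    )
    profiles = ecology.virome_profiles(final, final_dets, list(counts.columns))

    return PipelineResult(
        records=flagged,
        final_records=final,
        detections=final_dets,
        removals=removals,
        filtered_counts=filtered_counts,
        triage_log=log,
        unclassifiable=unclassifiable,
        host_predictions=host_predictions,
        clade_summaries=clade_summaries,
        profiles=profiles,
    )


def run_on_bundle(bundle, **kwargs) -> PipelineResult:
    """Run the full pipeline on an in-memory SimulatedBundle."""
    return run_pipeline(
        contigs=bundle.contigs,
        hits=bundle.homology_hits,
        domains=bundle.domain_hits,
        counts=bundle.count_matrix,
        meta=bundle.library_meta,
        refs=bundle.reference_table,
        virus_contigs=bundle.virus_contigs,
        **kwargs,
    )
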
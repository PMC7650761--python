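#!/usr/bin/env python
"""Infer hosts, delimit species and summarize clades.

Applies the ordered host rules to each curated virus, clusters replicase
proteins into species at >95% identity, and writes the host table,
species clusters and per-clade summary (counts, mean abundance, mean
identity) to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from termite_virome import orf_codes, pipeline, taxonomy_host as th


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = pipeline.load_bundle_dir(args.bundle)
    res = pipeline.run_pipeline(
        contigs=data["contigs"], hits=data["hits"], domains=data["domains"],
        counts=data["counts"], meta=data["meta"], refs=data["refs"],
        virus_contigs=data["virus_contigs"],
    )

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "virus_name": name, "host_prediction": p.category,
                "confidence": p.confidence, "evidence": ";".join(p.evidence),
            }
            for name, p in sorted(res.host_predictions.items())
        ]
    ).to_csv(args.out / "host_predictions.tsv", sep="\t", index=False)

    # species delimitation over the replicase proteins of the curated set
    seq_of = {c.contig_id: c.sequence for c in data["contigs"]}
    proteins = {}
    for r in res.final_records:
        orfs = orf_codes.find_orfs(seq_of[r.contig_ids[0]], r.code_id, min_len_codons=100)
        if orfs:
            proteins[r.virus_name] = orfs[0].protein
    clusters = th.cluster_species(th.identity_matrix(proteins)) if proteins else {}
    pd.DataFrame(
        [{"virus_name": v, "species_cluster": c} for v, c in sorted(clusters.items())]
    ).to_csv(args.out / "species_clusters.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "clade": s.clade, "group": s.group,
                "n_novel_viruses": s.n_novel_viruses,
                "host_prediction": s.host_prediction,
                "mean_abundance": s.mean_abundance,
                "mean_identity": s.mean_identity,
            }
            for s in res.clade_summaries
        ]
    ).to_csv(args.out / "clade_summaries.tsv", sep="\t", index=False)

    n_species = len(set(clusters.values()))
    hosts = pd.Series([p.category for p in res.host_predictions.values()]).value_counts()
    print(f"{len(res.final_records)} curated viruses in {n_species} species "
          f"across {len(res.clade_summaries)} clades")
    print("host predictions: " + ", ".join(f"{k}={v}" for k, v in hosts.items()))
    print(f"wrote host_predictions.tsv, species_clusters.tsv, clade_summaries.tsv")


if __name__ == "__main__":
    main()
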
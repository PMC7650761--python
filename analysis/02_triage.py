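#!/usr/bin/env python
"""Run candidate filtering and exclusion rules over the bundle.

Reads results/bundle/, applies the e-value / non-viral-domain retention
rule, the contaminant blacklist, the DNA-virus exclusion and the
interrupted-ORF endogenization rule, and writes the curated virus table
plus a per-contig decision log to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from termite_virome import pipeline


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

    rows = [
        {
            "virus_name": r.virus_name,
            "clade": r.clade,
            "group": r.group,
            "genome_length": r.genome_length,
            "closest_relative": r.closest_relative.name,
            "percent_identity": r.percent_identity_to_relative,
            "completeness": round(r.completeness_ratio, 4),
            "genetic_code": r.code_id,
            "endogenous": r.endogenous,
            "contaminant": r.contaminant_blacklist,
            "dna_excluded": r.dna_virus_excluded,
            "in_final_virome": not r.excluded,
        }
        for r in res.records
    ]
    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "virus_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"contig_id": d.contig_id, "retained": d.retained,
          "rule": d.rule, "detail": d.detail} for d in res.triage_log]
    ).to_csv(args.out / "triage_log.tsv", sep="\t", index=False)

    n_final = len(res.final_records)
    n_endo = sum(r.endogenous for r in res.records)
    n_excl = len(res.records) - n_final
    print(
        f"{len(res.records)} candidates -> {n_final} curated viruses "
        f"({n_endo} endogenized, {n_excl - n_endo} other exclusions); "
        f"{len(res.removals)} index-hop detections removed"
    )
    print(f"wrote {args.out/'virus_table.tsv'} and {args.out/'triage_log.tsv'}")


if __name__ == "__main__":
    main()
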
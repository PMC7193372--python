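#!/usr/bin/env python
"""Profile KEGG-function read counts from the simulated metagenome.

Reads the hit/location/read tables written by 01_simulate.py, picks the
best annotation per ORF, assigns reads to ORFs (>= 50% overlap), builds
the sample x annotation contingency table with relative abundances, and
checks the K03695 counts against the generator's planted truth.  Writes
function_counts.tsv, function_relative.tsv and category_counts.tsv.
"""

import argparse
import json
from pathlib import Path

from gutclpb.profiling import (
    assign_reads_to_orfs,
    best_annotation_per_orf,
    build_function_table,
    parse_hits,
    parse_orf_locations,
    parse_read_alignments,
    reads_from_frame,
)
from gutclpb.synthetic import CLPB_KO

KO_CATEGORIES = {CLPB_KO: {"chaperones and folding catalysts", "longevity regulating pathway"}}
KO_DESCRIPTIONS = {CLPB_KO: "ClpB; ATP-dependent Clp protease ATP-binding subunit ClpB"}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    hits = parse_hits(args.indir / "hits.tsv")
    orfs = parse_orf_locations(args.indir / "orf_locations.tsv")
    reads = parse_read_alignments(args.indir / "read_alignments.tsv")

    orf2ko = best_annotation_per_orf(hits)
    per_sample = {
        sample: assign_reads_to_orfs(
            reads_from_frame(grp[["read_id", "contig", "start", "end"]]), orfs
        )
        for sample, grp in reads.groupby("sample")
    }
    table = build_function_table(orf2ko, per_sample, KO_CATEGORIES, KO_DESCRIPTIONS)

    table.counts.to_csv(args.outdir / "function_counts.tsv", sep="\t")
    table.relative.to_csv(args.outdir / "function_relative.tsv", sep="\t")
    table.category_counts.to_csv(args.outdir / "category_counts.tsv", sep="\t")

    truth = json.loads((args.indir / "truth.json").read_text())
    print(f"{len(orf2ko)} annotated ORFs, {len(reads)} read alignments")
    for sample in table.counts.index:
        counted = int(table.counts.loc[sample, CLPB_KO])
        planted = truth["reads_per_ko"][sample][CLPB_KO]
        flag = "OK" if counted == planted else "MISMATCH"
        print(
            f"{sample}: {CLPB_KO} reads counted={counted} planted={planted} [{flag}] "
            f"(dropped on unannotated ORFs: {table.dropped_reads[sample]})"
        )


if __name__ == "__main__":
    main()
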
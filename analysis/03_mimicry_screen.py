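#!/usr/bin/env python
"""Screen simulated ORFs for the alpha-MSH-mimetic epitope.

Aligns every ORF from 01_simulate.py to the reference epitope region,
trims to the motif +/- 30 residues, scores motif and window identity,
and summarises by bacterial family.  Writes mimicry_hits.tsv,
family_summaries.tsv, homology_distribution.tsv and mimicry_discards.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from gutclpb.mimicry import (
    ReferenceProtein,
    homology_distribution,
    screen_orfs,
    summarize_families,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--motif", default="RWGKPV")
    ap.add_argument("--flank", type=int, default=30)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ref_record = next(SeqIO.parse(args.indir / "reference.faa", "fasta"))
    reference = ReferenceProtein(
        id=ref_record.id, accession="SYN_CLPB_0001.1", sequence=str(ref_record.seq)
    )
    orfs = list(SeqIO.parse(args.indir / "orfs.faa", "fasta"))
    taxonomy = dict(
        pd.read_csv(args.indir / "taxonomy.tsv", sep="\t").itertuples(index=False)
    )

    hits, discards = screen_orfs(orfs, taxonomy, reference, args.motif, args.flank)
    pd.DataFrame(
        [(h.orf_id, h.family, h.motif_identity, h.window_identity) for h in hits],
        columns=["orf_id", "family", "motif_identity", "window_identity"],
    ).to_csv(args.outdir / "mimicry_hits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(d.orf_id, d.family, d.reason) for d in discards],
        columns=["orf_id", "family", "reason"],
    ).to_csv(args.outdir / "mimicry_discards.tsv", sep="\t", index=False)

    summaries = summarize_families(hits)
    pd.DataFrame(
        [(s.family, s.n_sequences, s.n_full_motif, s.mean_window_identity) for s in summaries],
        columns=["family", "n_sequences", "n_full_motif", "mean_window_identity"],
    ).to_csv(args.outdir / "family_summaries.tsv", sep="\t", index=False)
    homology_distribution(hits, [0, 50, 60, 70, 80, 90, 100]).to_csv(
        args.outdir / "homology_distribution.tsv", sep="\t"
    )

    truth = json.loads((args.indir / "truth.json").read_text())
    print(f"{len(hits)} ORFs cover the epitope, {len(discards)} discarded")
    for s in summaries:
        planted = truth["full_motif_counts"][s.family]
        flag = "OK" if s.n_full_motif == planted else "MISMATCH"
        print(
            f"{s.family}: n={s.n_sequences}, 100%-motif={s.n_full_motif} "
            f"(planted {planted}) [{flag}], mean window identity "
            f"{s.mean_window_identity:.2f}% (planted flank identity "
            f"{100 * truth['expected_flank_identity'][s.family]:.0f}%)"
        )


if __name__ == "__main__":
    main()
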
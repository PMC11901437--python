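"""Genome-wide variant summaries of the simulated call sets.

Parses the emitted VCFs back from disk (exercising the same I/O path a real
study would use), then tabulates insertion/deletion and zygosity partitions,
gene-region distribution, and the InDel length histogram with its marker-
eligible (>50 bp) fraction. Writes type_summary.tsv, region_distribution.tsv
and length_histogram.tsv under results/tables/.
"""

import argparse
import os

import pandas as pd

from indelmark import (
    GeneModelSet,
    annotate_table,
    length_histogram,
    normalize_table,
    parse_vcf,
    percent,
    summarize_types,
)
from indelmark.pipeline import load_reference


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--outdir", default="results/tables")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    reference = load_reference(os.path.join(args.simdir, "maternal.fa"))
    models = GeneModelSet.from_gff3(os.path.join(args.simdir, "genes.gff3"))
    tables = {
        "maternal_parent": parse_vcf(os.path.join(args.simdir, "maternal.vcf"), "maternal_parent", "maternal"),
        "paternal_parent": parse_vcf(os.path.join(args.simdir, "paternal.vcf"), "paternal_parent", "maternal"),
    }

    rows, region_rows, length_rows = [], [], []
    for sample, table in tables.items():
        table = normalize_table(table, reference)
        labels = annotate_table(table, models)
        summary = summarize_types(table, labels)
        rows.append(
            {
                "sample": sample,
                "n_total": summary.n_total,
                "n_insertion": summary.n_insertion,
                "n_deletion": summary.n_deletion,
                "n_heterozygous": summary.n_heterozygous,
                "n_homozygous": summary.n_homozygous,
                "n_missing": summary.n_missing,
            }
        )
        for label, count in sorted(summary.region_counts.items()):
            region_rows.append(
                {
                    "sample": sample,
                    "region": label,
                    "count": count,
                    "pct": percent(count, summary.n_total),
                }
            )
        hist = length_histogram(table)
        for label, count in zip(hist.labels, hist.counts):
            length_rows.append({"sample": sample, "length_bin_bp": label, "count": count})
        n_long = hist.count_greater_than(50)
        print(
            f"{sample}: {summary.n_total} InDels "
            f"({summary.n_insertion} ins / {summary.n_deletion} del; "
            f"{summary.n_heterozygous} het / {summary.n_homozygous} hom); "
            f"{n_long} ({percent(n_long, summary.n_total)}%) > 50 bp"
        )

    pd.DataFrame(rows).to_csv(os.path.join(args.outdir, "type_summary.tsv"), sep="\t", index=False)
    pd.DataFrame(region_rows).to_csv(os.path.join(args.outdir, "region_distribution.tsv"), sep="\t", index=False)
    pd.DataFrame(length_rows).to_csv(os.path.join(args.outdir, "length_histogram.tsv"), sep="\t", index=False)
    print(f"tables written to {args.outdir}")


if __name__ == "__main__":
    main()
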
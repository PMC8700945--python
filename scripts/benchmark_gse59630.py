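"""Optional real-data benchmark against a locally downloaded GSE59630 series.

This harness is NOT part of the test suite and is never run automatically:
it needs the deposited series-matrix file of GEO accession GSE59630 (Down
Syndrome and euploid control brain, 11 regions, prenatal to adult ages),
which you must download yourself, e.g.:

    https://ftp.ncbi.nlm.nih.gov/geo/series/GSE59nnn/GSE59630/matrix/

then decompress and run:

    python scripts/benchmark_gse59630.py \
        --series GSE59630_series_matrix.txt \
        --annotation probe_annotation.tsv \
        --out benchmark_out/

``--annotation`` maps the Affymetrix probe-set ids to the five HMGN gene
symbols (the probe choice per gene is a free parameter of the benchmark:
the original analysis does not state which probe sets were used — edit
the TSV to explore alternatives).  The harness runs the replication
profile (Z-score clipping at ±3, full filtered gene universe) and prints
the gene × stratum Z-ratio table for HMGN1–5 so it can be compared cell
by cell with published values; deviations are expected to reflect probe
selection, clip ordering, and gene-universe choices.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from zratio import RunConfig, run_zratio_report

HMGN_GENES = ("HMGN1", "HMGN2", "HMGN3", "HMGN4", "HMGN5")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--series", type=Path, required=True,
                        help="decompressed GSE59630 series-matrix file")
    parser.add_argument("--annotation", type=Path, required=True,
                        help="probe_id/gene_symbol TSV restricted to the HMGN probe sets")
    parser.add_argument("--metadata", type=Path, default=None,
                        help="optional curated metadata TSV overriding the header parse")
    parser.add_argument("--out", type=Path, default=Path("benchmark_out"))
    args = parser.parse_args()

    cfg = RunConfig(
        input=args.series,
        metadata=args.metadata,
        annotation=args.annotation,
        outdir=args.out,
        genes=HMGN_GENES,
    ).with_profile("paper")
    wide, _ = run_zratio_report(cfg)
    print(wide.to_string())
    print(f"\nfull reports written to {args.out}/")


if __name__ == "__main__":
    main()
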
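#!/usr/bin/env python
"""Preprocess the simulated library and map it to the target transcript.

Trims the 3'/5' adapters, drops low-quality and out-of-size reads, then maps
every insert to both strands of the transcript at zero mismatches.  Writes
the trimmed FASTQ, preprocessing stats and the alignment table.
"""

import json
from pathlib import Path

from pxyfem.io import read_fasta, read_fastq, write_fastq
from pxyfem.preprocess import preprocess_reads
from pxyfem.srna_map import alignments_to_table, map_reads

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    reads = list(read_fastq(OUT / "library.fastq"))
    target_id, target_seq = next(iter(read_fasta(OUT / "target.fa").items()))

    pre, stats = preprocess_reads(reads)
    write_fastq(pre, OUT / "library.trimmed.fastq")
    (OUT / "preprocess_stats.json").write_text(json.dumps(stats.as_dict(), indent=2))

    alignments, unmapped = map_reads(pre, (target_id, target_seq), max_mismatch=0)
    alignments_to_table(alignments).to_csv(OUT / "alignments.tsv", sep="\t", index=False)

    print("preprocessing:", stats.as_dict())
    print(f"mapped {len(alignments)} of {len(pre)} reads ({len(unmapped)} unmapped)")
    sense = sum(a.strand == "sense" for a in alignments)
    print(f"strand split: {sense} sense / {len(alignments) - sense} antisense")


if __name__ == "__main__":
    main()
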
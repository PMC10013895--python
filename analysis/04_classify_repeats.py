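#!/usr/bin/env python
"""Step 4 — classify merged deletions/insertions by repeat content.

Sequence-based detection first (tandem repeats, then mobile-element
alignment against the LINE/SINE/LTR library), falling back to the
repeat-region track for sequence-free records. Writes results/classes.tsv.
"""

import argparse
import os
from collections import Counter

from svsoma import io as svio
from svsoma.model import SampleMeta
from svsoma.repeats import classify_record


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--indir", default="results")
    args = parser.parse_args()

    ref_dir = os.path.join(args.indir, "reference")
    library = svio.read_repeat_library(
        os.path.join(ref_dir, "repeat_library.fa"))
    track = svio.read_repeat_regions(os.path.join(ref_dir, "repeats.bed"))
    cohort_meta = SampleMeta(sample_id="cohort", patient_id="cohort",
                             role="tumor", mean_depth=1.0)
    merged = svio.read_sv_vcf(os.path.join(args.indir, "merged.vcf"),
                              cohort_meta)

    out = os.path.join(args.indir, "classes.tsv")
    tallies = {"DEL": Counter(), "INS": Counter()}
    with open(out, "w") as fh:
        fh.write("record_id\tsvtype\trepeat_class\n")
        for r in merged:
            if r.svtype not in ("DEL", "INS"):
                continue
            cls = classify_record(r, library, track)
            tallies[r.svtype][cls.value] += 1
            fh.write(f"{r.record_id}\t{r.svtype}\t{cls.value}\n")

    for svtype, tally in tallies.items():
        total = sum(tally.values())
        if not total:
            continue
        parts = ", ".join(f"{k} {v / total:.1%}"
                          for k, v in tally.most_common())
        print(f"{svtype} ({total} clusters): {parts}")
    print(f"classes written to {out}")


if __name__ == "__main__":
    main()
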
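#!/usr/bin/env python
"""Step 6 — cohort summary report.

Type proportions with and without STR-region insertions, log-binned
length and inter-SV distance distributions, recurrence and the MSI-H
versus MSS insertion comparison. Writes tables, plots and a plain-text
summary under results/report/.
"""

import argparse
import os

import pandas as pd

from svsoma import io as svio
from svsoma.merge import merge_cohort
from svsoma.model import MatchParams, RepeatClass
from svsoma.report import render_report, summarize


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--indir", default="results")
    args = parser.parse_args()

    cohort = os.path.join(args.indir, "cohort")
    somatic_dir = os.path.join(args.indir, "somatic")
    metas = {m.sample_id: m for m in svio.read_metadata(
        os.path.join(cohort, "metadata.tsv"))}
    callsets = []
    for name in sorted(os.listdir(somatic_dir)):
        if name.endswith(".vcf"):
            cs = svio.read_sv_vcf(os.path.join(somatic_dir, name),
                                  metas[name.split(".")[0]])
            cs.somatic = True
            callsets.append(cs)
    merged = merge_cohort(callsets, MatchParams())

    cls_df = pd.read_csv(os.path.join(args.indir, "classes.tsv"), sep="\t",
                         keep_default_na=False)
    classes = {row.record_id: RepeatClass(row.repeat_class)
               for row in cls_df.itertuples()}

    report = summarize(merged, callsets, classes)
    outdir = os.path.join(args.indir, "report")
    render_report(report, outdir)
    print(open(os.path.join(outdir, "summary.txt")).read())
    print(f"full report under {outdir}/")


if __name__ == "__main__":
    main()
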
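#!/usr/bin/env python
"""Step 3 — merge per-patient somatic calls into a nonredundant set.

Single-linkage clustering under the standard matching predicate;
recurrence counts distinct patients per cluster. Writes the merged VCF
(cluster id and recurrence as INFO keys) and the recurrence table.
"""

import argparse
import os

from svsoma import io as svio
from svsoma.merge import fraction_recurrent, merge_cohort, recurrence_table
from svsoma.model import Callset, SampleMeta


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

    merged = merge_cohort(callsets)
    cohort_meta = SampleMeta(sample_id="cohort", patient_id="cohort",
                             role="tumor", mean_depth=1.0)
    reps = [m.representative.copy(record_id=m.cluster_id) for m in merged]
    extra = {m.cluster_id: {"CLUSTER_ID": m.cluster_id,
                            "RECURRENCE": m.recurrence} for m in merged}
    svio.write_sv_vcf(Callset(sample=cohort_meta, records=reps,
                              somatic=True),
                      os.path.join(args.indir, "merged.vcf"),
                      extra_info=extra)
    table = recurrence_table(merged)
    table.to_csv(os.path.join(args.indir, "recurrence.tsv"), sep="\t",
                 index=False, float_format="%.6g")

    n_calls = sum(len(c) for c in callsets)
    print(f"{n_calls} somatic calls from {len(callsets)} tumors merged "
          f"into {len(merged)} nonredundant clusters")
    print(f"fraction detected in >=2 patients: "
          f"{fraction_recurrent(merged):.1%}")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
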
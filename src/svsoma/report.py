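"""Cohort-level summaries of the merged somatic call set.

The report mirrors the descriptive figures of a tumor/normal SV study:
per-sample counts and cohort type proportions with and without
STR-region insertions, log-binned SV length and inter-SV distance
distributions, recurrence across patients, and the MSI-H versus MSS
somatic-insertion comparison (Student's two-sample t-test by default,
Welch optionally).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .merge import fraction_recurrent, recurrence_table
from .model import Callset, MergedSV, RepeatClass
from .repeats import str_exclusion_split, type_proportions

#: log-spaced length bins, 50 bp to 10 Mbp, 10 bins per decade
LENGTH_BIN_EDGES = np.logspace(math.log10(50), 7, num=54)
#: inter-SV distance bins, 100 bp to 100 Mbp
DISTANCE_BIN_EDGES = np.logspace(2, 8, num=61)


@dataclass
class CohortReport:
    per_sample_counts: pd.DataFrame
    proportions_all: dict[str, float]
    proportions_excl_str: dict[str, float]
    length_histogram: pd.DataFrame
    distance_histogram: pd.DataFrame
    recurrence: pd.DataFrame
    fraction_recurrent_all: float
    msi_comparison: dict
    n_clusters_all: int = 0
    n_clusters_excl_str: int = 0


def _per_sample_counts(callsets: Iterable[Callset]) -> pd.DataFrame:
    rows = []
    for c in callsets:
        row = {"sample_id": c.sample.sample_id,
               "patient_id": c.sample.patient_id,
               "msi_status": c.sample.msi_status,
               "stage": c.sample.stage}
        for t in ("DEL", "INS", "DUP", "INV", "TRA"):
            row[t] = sum(1 for r in c if r.svtype == t)
        row["total"] = len(c)
        rows.append(row)
    cols = ["sample_id", "patient_id", "msi_status", "stage",
            "DEL", "INS", "DUP", "INV", "TRA", "total"]
    return pd.DataFrame(rows, columns=cols)


def _length_histogram(merged: list[MergedSV]) -> pd.DataFrame:
    lengths = [m.representative.svlen for m in merged
               if m.svtype != "TRA" and m.representative.svlen > 0]
    counts, edges = np.histogram(lengths, bins=LENGTH_BIN_EDGES)
    return pd.DataFrame({"bin_lo_bp": edges[:-1], "bin_hi_bp": edges[1:],
                         "n_clusters": counts})


def _distance_histogram(callsets: Iterable[Callset]) -> pd.DataFrame:
    """Gaps between consecutive SV start positions, per chromosome per
    sample, pooled over the cohort."""
    gaps: list[int] = []
    for c in callsets:
        by_chrom: dict[str, list[int]] = {}
        for r in c:
            by_chrom.setdefault(r.chrom, []).append(r.pos)
        for positions in by_chrom.values():
            positions.sort()
            gaps.extend(b - a for a, b in zip(positions, positions[1:]))
    counts, edges = np.histogram(gaps, bins=DISTANCE_BIN_EDGES)
    return pd.DataFrame({"bin_lo_bp": edges[:-1], "bin_hi_bp": edges[1:],
                         "n_gaps": counts})


def msi_insertion_test(callsets: Iterable[Callset],
                       ttest: Literal["student", "welch"] = "student",
                       counts: Optional[dict[str, int]] = None) -> dict:
    """Compare somatic insertion counts between MSI-H and MSS tumors.

    ``counts`` optionally supplies per-sample insertion counts directly
    (e.g. truth STR-insertion counts); otherwise INS calls are counted
    from the callsets. Student's equal-variance two-sided t-test is the
    default; ``welch`` switches to the unequal-variance form.
    """
    msi, mss = [], []
    for c in callsets:
        n = (counts[c.sample.sample_id] if counts is not None
             else sum(1 for r in c if r.svtype == "INS"))
        (msi if c.sample.msi_status == "MSI-H" else mss).append(n)
    out = {"n_msi_h": len(msi), "n_mss": len(mss),
           "mean_msi_h": float(np.mean(msi)) if msi else float("nan"),
           "mean_mss": float(np.mean(mss)) if mss else float("nan"),
           "t_statistic": float("nan"), "p_value": float("nan"),
           "test": ttest}
    if len(msi) >= 2 and len(mss) >= 2:
        t, p = stats.ttest_ind(msi, mss, equal_var=(ttest == "student"))
        out["t_statistic"], out["p_value"] = float(t), float(p)
    return out


def summarize(merged: Iterable[MergedSV], callsets: Iterable[Callset],
              classes: dict[str, RepeatClass],
              ttest: Literal["student", "welch"] = "student") -> CohortReport:
    """Build the cohort report from the merged call set, the per-sample
    somatic callsets and the per-cluster repeat classes."""
    merged = list(merged)
    callsets = list(callsets)
    all_clusters, excl_str = str_exclusion_split(merged, classes)
    return CohortReport(
        per_sample_counts=_per_sample_counts(callsets),
        proportions_all=type_proportions(all_clusters),
        proportions_excl_str=type_proportions(excl_str),
        length_histogram=_length_histogram(merged),
        distance_histogram=_distance_histogram(callsets),
        recurrence=recurrence_table(merged),
        fraction_recurrent_all=fraction_recurrent(merged),
        msi_comparison=msi_insertion_test(
            [c for c in callsets if c.sample.role == "tumor"
             or c.somatic], ttest=ttest),
        n_clusters_all=len(all_clusters),
        n_clusters_excl_str=len(excl_str),
    )


def _proportions_frame(report: CohortReport) -> pd.DataFrame:
    types = ("DEL", "INS", "DUP", "INV", "TRA")
    rows = []
    for name, props in (("all", report.proportions_all),
                        ("excl_STR_insertions",
                         report.proportions_excl_str)):
        row = {"set": name}
        row.update({t: props.get(t, 0.0) for t in types})
        rows.append(row)
    return pd.DataFrame(rows, columns=["set", *types])


def render_report(report: CohortReport, outdir: str,
                  plots: bool = True) -> list[str]:
    """Write TSV tables, a plain-text summary and (optionally) static
    plots. Table bytes are stable for a fixed report."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    save(report.per_sample_counts, "per_sample_counts.tsv")
    save(_proportions_frame(report), "type_proportions.tsv")
    save(report.length_histogram, "length_histogram.tsv")
    save(report.distance_histogram, "distance_histogram.tsv")
    save(report.recurrence, "recurrence.tsv")
    save(pd.DataFrame([report.msi_comparison]), "msi_comparison.tsv")

    summary = os.path.join(outdir, "summary.txt")
    with open(summary, "w") as fh:
        fh.write(f"clusters (all): {report.n_clusters_all}\n")
        fh.write("clusters (excl. STR insertions): "
                 f"{report.n_clusters_excl_str}\n")
        fh.write("fraction of clusters in >=2 patients: "
                 f"{report.fraction_recurrent_all:.3f}\n")
        for name, props in (("all", report.proportions_all),
                            ("excl STR ins", report.proportions_excl_str)):
            parts = ", ".join(f"{t} {v:.1%}" for t, v in sorted(props.items()))
            fh.write(f"type proportions ({name}): {parts}\n")
        m = report.msi_comparison
        fh.write(f"somatic insertions, MSI-H vs MSS: "
                 f"{m['mean_msi_h']:.1f} vs {m['mean_mss']:.1f} "
                 f"(t={m['t_statistic']:.3g}, p={m['p_value']:.3g}, "
                 f"{m['test']} t-test)\n")
    written.append(summary)

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, (name, props) in zip(
                axes, (("all", report.proportions_all),
                       ("excl. STR insertions",
                        report.proportions_excl_str))):
            if props:
                ax.pie(list(props.values()), labels=list(props.keys()),
                       autopct="%1.1f%%")
            ax.set_title(f"SV type proportions ({name})")
        fig.tight_layout()
        path = os.path.join(outdir, "type_proportions.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        fig, ax = plt.subplots(figsize=(6, 4))
        h = report.length_histogram
        if h["n_clusters"].sum() > 0:
            ax.bar(np.sqrt(h["bin_lo_bp"] * h["bin_hi_bp"]),
                   h["n_clusters"],
                   width=np.diff(LENGTH_BIN_EDGES), align="center")
            ax.set_xscale("log")
        ax.set_xlabel("SV length (bp)")
        ax.set_ylabel("clusters")
        fig.tight_layout()
        path = os.path.join(outdir, "length_distribution.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
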
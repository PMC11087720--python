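#!/usr/bin/env python
"""Derive the episignature on the discovery cohort.

Runs the full discovery sequence on the cohort from 01: iterative pruning
of signature-negative cases (leave-one-case-out MVP < 0.25), probe
selection, SVM training on all retained cases + 75% of controls, 20 rounds
of leave-25%-out cross-validation, and the clustering/MDS views.  Writes
classifier artifacts to scratch/run/ and summary tables to results/.
"""

from pathlib import Path

import pandas as pd

from episig.io import read_beta_matrix, read_sample_sheet
from episig.pipeline import RunConfig, run_discovery

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    beta = read_beta_matrix(DATA / "discovery_beta.tsv")
    sheet = read_sample_sheet(DATA / "discovery_samples.csv")
    truth = pd.read_csv(DATA / "discovery_truth.tsv", sep="\t")
    planted = set(truth.loc[truth["is_dmp"], "probe_id"])

    config = RunConfig(seed=SEED, outdir="")
    art = run_discovery(config, beta=beta, sheet=sheet, outdir=RUN)

    selected = set(art.probe_set.probe_ids)
    summary = {
        "probes_total": art.stage_counts["probes_in"],
        "dmps_at_fdr_0.05": art.stage_counts["dmps_q05"],
        "signature_probes": len(selected),
        "signature_recall_vs_truth": round(len(selected & planted) / len(planted), 3),
        "signature_precision_vs_truth": round(len(selected & planted) / len(selected), 3),
        "cases_removed_by_pruning": len(art.removed_case_ids),
        "held_out_control_specificity_pct": art.specificity,
    }
    pd.Series(summary).to_csv(RESULTS / "02_discovery_summary.tsv", sep="\t", header=False)

    cv = art.cv_report
    cv_ok_cases = (cv.loc[cv["held_out_group"] == "case", "mvp"] > 0.5).mean()
    cv_ok_ctrls = (cv.loc[cv["held_out_group"] == "control", "mvp"] < 0.25).mean()
    cv.groupby("round").agg(
        n_held_out=("sample_id", "size"), min_case_mvp=("mvp", "min"),
        probes=("probe_set_size", "first"),
    ).to_csv(RESULTS / "02_cv_rounds.tsv", sep="\t")

    print("discovery summary:")
    for k, v in summary.items():
        print(f"  {k}: {v}")
    print(f"  removed cases: {art.removed_case_ids}")
    print(f"  CV held-out case sensitivity (MVP>0.5): {100*cv_ok_cases:.1f}%")
    print(f"  CV held-out control specificity (MVP<0.25): {100*cv_ok_ctrls:.1f}%")
    print(f"artifacts in {RUN}; tables in {RESULTS}")


if __name__ == "__main__":
    main()
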
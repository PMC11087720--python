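#!/usr/bin/env python
"""Validate the frozen classifier on an independent case cohort.

Scores the 11 validation cases with the classifier from 02 (expected: every
MVP > 0.5), re-clusters them with the discovery cohort on the signature
probes, and then re-derives the signature with the validation cases folded
into the discovery cohort — the robustness re-derivation that typically
enlarges the probe list.
"""

from pathlib import Path

import pandas as pd

from episig.classify import TrainedClassifier
from episig.dmp import ProbeSet, dmp_table, select_probes
from episig.io import read_beta_matrix, read_sample_sheet
from episig.pipeline import RunConfig, run_validation

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    beta = read_beta_matrix(DATA / "discovery_beta.tsv")
    sheet = read_sample_sheet(DATA / "discovery_samples.csv")
    vbeta = read_beta_matrix(DATA / "validation_beta.tsv")
    vsheet = read_sample_sheet(DATA / "validation_samples.csv")
    clf = TrainedClassifier.from_json(RUN / "classifier.json")
    probe_set = ProbeSet.from_json(RUN / "probe_set.json")
    removed = (RUN / "removed_cases.txt").read_text().split()

    config = RunConfig(seed=SEED, outdir="")
    report = run_validation(config, probe_set, clf, vbeta, training_beta=beta,
                            outdir=RUN)
    report.to_csv(RESULTS / "03_validation_scores.tsv", sep="\t", index=False)

    # re-derivation with validation cases included in the discovery cohort
    vsheet_cases = vsheet.assign(group="case")
    combined_sheet = pd.concat(
        [sheet[~sheet["sample_id"].isin(removed)], vsheet_cases], ignore_index=True
    )
    combined_beta = pd.concat([beta, vbeta], axis=1)[combined_sheet["sample_id"]]
    table = dmp_table(combined_beta, combined_sheet)
    final_set = select_probes(table, combined_beta, combined_sheet)

    print("validation cohort MVP scores:")
    print(report.round(3).to_string(index=False))
    print(f"\nall validation samples positive: {(report['call'] == 'positive').all()}")
    print(f"signature probes (discovery only): {len(probe_set.probe_ids)}")
    print(f"signature probes (incl. validation cases): {len(final_set.probe_ids)}")
    pd.Series(
        {
            "validation_samples": len(report),
            "all_positive": bool((report["call"] == "positive").all()),
            "min_validation_mvp": round(float(report["mvp"].min()), 3),
            "final_probe_count": len(final_set.probe_ids),
        }
    ).to_csv(RESULTS / "03_validation_summary.tsv", sep="\t", header=False)


if __name__ == "__main__":
    main()
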
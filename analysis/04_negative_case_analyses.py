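#!/usr/bin/env python
"""Why do some cases score negative?  Mosaic dose-response and the
transcript-fraction arithmetic.

Scores fresh case samples at mosaic fractions 1.0, 0.5, 0.25 and 0 with
the frozen classifier: the MVP falls with the fraction of affected cells,
and a variant confined to ~25% of blood cells already drops below the
negative cutoff — bulk methylation dilutes linearly, so mosaicism is a
built-in blind spot of blood episignatures.  Also reports the
loss-of-function transcript fraction for a splice-affecting variant whose
mRNA assay shows 15% exon skipping, 27% intron retention, 8% normal
splicing and 50% degraded transcripts.
"""

from pathlib import Path

import pandas as pd
import yaml

from episig.classify import TrainedClassifier, classify_call, mvp_score
from episig.compare import lof_transcript_fraction
from episig.simulate import SimulationConfig, simulate_cases_from_truth, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    with open(DATA / "discovery_config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["age_range"] = tuple(raw["age_range"])
    _, _, truth = simulate_cohort(SimulationConfig(**raw))  # regenerate frozen truth
    clf = TrainedClassifier.from_json(RUN / "classifier.json")

    rows = []
    for m in (1.0, 0.5, 0.25, 0.0):
        mbeta, _ = simulate_cases_from_truth(truth, 10, seed=SEED + 3, m=m,
                                             prefix=f"m{int(m*100):03d}")
        scores = mvp_score(clf, mbeta)
        rows.append(
            {
                "mosaic_fraction": m,
                "mean_mvp": round(float(scores.mean()), 3),
                "min_mvp": round(float(scores.min()), 3),
                "max_mvp": round(float(scores.max()), 3),
                "modal_call": scores.map(classify_call).mode()[0],
            }
        )
    dose = pd.DataFrame(rows)
    dose.to_csv(RESULTS / "04_mosaic_dose_response.tsv", sep="\t", index=False)
    print("mosaic dose-response (10 fresh cases per level):")
    print(dose.to_string(index=False))

    lof = lof_transcript_fraction(exon_skipping=15, intron_retention=27, normal=8, nmd=50)
    print(f"\nsplice-variant LoF transcript fraction: {lof:.0f}% "
          "(exon skipping 15% + intron retention 27%)")
    pd.Series({"lof_transcript_percent": lof}).to_csv(
        RESULTS / "04_lof_transcript.tsv", sep="\t", header=False
    )


if __name__ == "__main__":
    main()
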
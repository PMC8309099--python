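#!/usr/bin/env python
"""Flowability and friability classification of the study measurements.

Applies the compendial-style flowability scales to the published angle of
repose and Carr's index means, and the 1%-loss/fracture rule to the
friability outcomes, then checks the resulting labels against the labels
the study reports. Writes results/qc_classification.csv.
"""

from pathlib import Path

import pandas as pd

from dissofit import classify_angle, classify_ci, friability_verdict
from dissofit.studydata import FLOW_MEASUREMENTS, FRIABILITY_RESULTS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    flow = FLOW_MEASUREMENTS.copy()
    flow["angle_class"] = [classify_angle(a).value for a in flow["angle_of_repose"]]
    flow["ci_class"] = [classify_ci(c).value for c in flow["carr_index"]]
    flow["labels_match"] = (flow["angle_class"] == flow["angle_label"]) & (
        flow["ci_class"] == flow["ci_label"]
    )

    fri = FRIABILITY_RESULTS.copy()
    fri["verdict"] = [
        friability_verdict(0.0 if pd.isna(loss) else loss, bool(frac))
        for loss, frac in zip(fri["weight_loss"], fri["fractured"])
    ]
    fri["verdict_matches"] = fri["verdict"] == fri["passed"]

    report = flow.merge(fri, on="formulation_id")
    OUT.mkdir(exist_ok=True)
    report.to_csv(OUT / "qc_classification.csv", index=False)
    print(report.to_string(index=False))
    print(
        f"\nflow labels reproduced: {int(flow['labels_match'].sum())}/10; "
        f"friability verdicts reproduced: {int(fri['verdict_matches'].sum())}/10"
    )


if __name__ == "__main__":
    main()
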
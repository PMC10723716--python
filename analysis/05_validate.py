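#!/usr/bin/env python
"""Score the annotated test set against the generator ground truth.

The truth records act as the expert annotator: predicted objects are
matched to truth reference points, the 3-class confusion matrix is
tabulated, and the headline accuracy is reported restricted to the
Swarmer/Stalked classes (debris calls are inherently subjective and are
reported separately). Outputs land in results/.
"""

import json
from pathlib import Path

import pandas as pd

from caulotype.config import OpticsConfig, RunConfig
from caulotype.workflow import read_provenance_csv, run_validate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    records_path = ROOT / "results" / "morpho_records.csv"
    data = ROOT / "scratch" / "data" / "test"
    if not records_path.exists():
        raise SystemExit("no annotations; run analysis/03_annotate.py first")
    records = read_provenance_csv(records_path)

    pooled = {"n_matched": 0, "excluded_count": 0}
    counts = None
    config = RunConfig(optics=OpticsConfig(frame_shape=(1024, 1024)))
    for stem, group in records.groupby("image"):
        truth = pd.read_csv(data / f"{stem}_records.csv")
        res = run_validate(config, group.reset_index(), truth)
        pooled["n_matched"] += res["n_matched"]
        pooled["excluded_count"] += res["excluded_count"]
        m = res["confusion"]
        counts = m.counts if counts is None else counts + m.counts

    from caulotype.validate import ConfusionMatrix, accuracy

    matrix = ConfusionMatrix(
        row_labels=("Swarmer", "Stalked", "Debris"),
        col_labels=("Swarmer", "Stalked", "Debris"),
        counts=counts, excluded_count=pooled["excluded_count"],
    )
    matrix.to_frame().to_csv(ROOT / "results" / "confusion_matrix.csv")
    report = {
        "n_matched": pooled["n_matched"],
        "excluded_count": pooled["excluded_count"],
        "accuracy_all_pct": round(100 * accuracy(matrix), 2),
        "accuracy_sw_st_pct": round(
            100 * accuracy(matrix, restrict_to=("Swarmer", "Stalked")), 2
        ),
    }
    (ROOT / "results" / "validation.json").write_text(json.dumps(report, indent=2))
    print("confusion matrix (rows = truth, cols = prediction):")
    print(matrix.to_frame().to_string())
    print(f"matched {report['n_matched']} objects, "
          f"{report['excluded_count']} excluded for lacking a counterpart")
    print(f"overall accuracy: {report['accuracy_all_pct']}%")
    print(f"Swarmer/Stalked restricted accuracy: {report['accuracy_sw_st_pct']}%")


if __name__ == "__main__":
    main()
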
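#!/usr/bin/env python
"""Train the pixel and object classifiers on the simulated training set.

Stage 1 learns per-pixel background / cell-body / stalk probabilities
from a multi-scale filter bank; stage 2 learns the stalked / swarmer /
debris object classes from segmented-object features labelled by the
generator truth. Models land in scratch/models/, the training report in
results/.
"""

import json
import shutil
from pathlib import Path

from caulotype.config import OpticsConfig, RunConfig
from caulotype.workflow import run_train

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "scratch" / "data" / "train"
    if not (data / "manifest.csv").exists():
        raise SystemExit("no training data; run analysis/01_simulate.py first")
    config = RunConfig(optics=OpticsConfig(frame_shape=(1024, 1024)), seed=11)
    models_dir = ROOT / "scratch" / "models"
    report = run_train(config, data, models_dir)
    (ROOT / "results").mkdir(exist_ok=True)
    shutil.copy(models_dir / "training_report.json",
                ROOT / "results" / "training_report.json")
    print(f"pixel model: mean training-frame pixel accuracy "
          f"{report['mean_pixel_accuracy']:.4f}")
    print(f"object model: {report['n_training_objects']} objects, "
          f"classes {json.dumps(report['object_class_counts'])}")


if __name__ == "__main__":
    main()
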
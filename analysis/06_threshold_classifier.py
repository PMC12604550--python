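"""A one-parameter SWS predictor trained leave-one-session-out.

The fitted initial value A per epoch is smoothed and thresholded; the
(threshold, smoothing) pair is trained on the other sessions and
significance is assessed against a 1,000-permutation label-shuffle
null.  If a single spatial-fit parameter predicts SWS this cleanly,
the spatial structure of the correlations carries the state.
"""

import importlib
import json

import numpy as np
import pandas as pd

from lfpspace import decay
from lfpspace.io import load_ground_truth, load_recording, load_sidecar, layout_from_dict
from lfpspace.preprocess import build_epoch_grid, zscore_channels
from lfpspace.spatial import session_distance_function
from lfpspace.threshold import accuracy_precision, predict, shuffle_null, train_loo

cfg = importlib.import_module("00_config")


def main():
    sessions = []
    for seed in cfg.CLASSIFIER_SEEDS:
        rec = load_recording(cfg.SCRATCH / f"session_{seed}.h5")
        layout = layout_from_dict(
            load_sidecar(cfg.SCRATCH / f"session_{seed}.h5")["layout"]
        )
        truth = load_ground_truth(cfg.SCRATCH / f"session_{seed}_truth.csv")
        rz = zscore_channels(rec)
        grid = build_epoch_grid(rz, 10.0)
        dcf = session_distance_function(rz, layout, grid)
        fits = decay.fit_all_epochs(dcf, ("exponential",), 0.2).sort_values("epoch")
        series = fits["A"].to_numpy(float)
        labels = truth["state"].to_numpy()[fits["epoch"].to_numpy(int)] == "SWS"
        sessions.append((series, labels))

    models = train_loo(sessions)
    report = []
    for k, ((series, labels), model) in enumerate(zip(sessions, models)):
        null = shuffle_null(series, labels, model, n_shuffles=1000, seed=cfg.SEED)
        perf = accuracy_precision(predict(series, model), labels)
        report.append(
            {
                "session": int(cfg.CLASSIFIER_SEEDS[k]),
                "threshold_A": model.threshold,
                "smooth_w": model.smooth_w,
                "direction": model.direction,
                "error": null["observed_error"],
                "null_mean_error": null["null_mean"],
                "null_ci95": list(null["null_ci95"]),
                "accuracy": perf["accuracy"],
                "precision": perf["precision"],
            }
        )
        print(
            f"session {cfg.CLASSIFIER_SEEDS[k]}: error "
            f"{null['observed_error']:.3f} vs null "
            f"{null['null_mean']:.3f} [{null['null_ci95'][0]:.3f}, "
            f"{null['null_ci95'][1]:.3f}], accuracy {perf['accuracy']:.3f}"
        )
    (cfg.RESULTS / "threshold_classifier.json").write_text(
        json.dumps(report, indent=2)
    )
    n_below = sum(r["error"] < r["null_ci95"][0] for r in report)
    print(f"{n_below}/{len(report)} sessions below the null 95% interval")


if __name__ == "__main__":
    main()
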
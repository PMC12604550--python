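"""Generate the synthetic study sessions.

One 360-epoch (1 h) default-regime session drives the main analysis;
three 80-epoch sessions feed the leave-one-out threshold classifier.
States alternate in multi-minute bouts; all-channel dropouts are
injected at telemetry-realistic rates.
"""

import importlib

import numpy as np

from lfpspace import utah_array
from lfpspace.io import save_ground_truth, save_recording
from lfpspace.pipeline import dropout_report
from lfpspace.simulate import default_params, generate_session

cfg = importlib.import_module("00_config")


def main():
    layout = utah_array()
    params = default_params()
    rec, truth = generate_session(layout, params, n_epochs=cfg.N_EPOCHS, seed=cfg.SEED)
    save_recording(cfg.SESSION_H5, rec, layout=layout, params=params)
    save_ground_truth(cfg.TRUTH_CSV, truth)

    counts = {s: truth.states.count(s) for s in ("SWS", "NULL", "REM_AWAKE")}
    rep = dropout_report(rec, params.epoch_s)
    print(
        f"main session: {cfg.N_EPOCHS} x {params.epoch_s:g} s epochs at "
        f"{params.fs:g} Hz, state counts {counts}"
    )
    print(
        f"dropouts: {rep['n_dropouts']} intervals, mean duration "
        f"{rep['mean_duration_s']:.2f} s -> "
        f"{int((~rec.valid).sum())} invalid samples"
    )

    for seed in cfg.CLASSIFIER_SEEDS:
        rec_k, truth_k = generate_session(
            layout, params, n_epochs=cfg.CLASSIFIER_EPOCHS, seed=seed
        )
        save_recording(cfg.SCRATCH / f"session_{seed}.h5", rec_k,
                       layout=layout, params=params)
        save_ground_truth(cfg.SCRATCH / f"session_{seed}_truth.csv", truth_k)
        print(f"classifier session seed {seed}: "
              f"{truth_k.states.count('SWS')} SWS epochs of {cfg.CLASSIFIER_EPOCHS}")


if __name__ == "__main__":
    main()
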
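"""Shared paths and constants for the analysis scripts.

Run the scripts in order (01 → 06) from the repository root.  Bulky
intermediates (HDF5 sessions, per-epoch tables) land in scratch/;
summary tables land in results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

SEED = 11
N_EPOCHS = 360
CLASSIFIER_SEEDS = (31, 32, 33)
CLASSIFIER_EPOCHS = 80

SESSION_H5 = SCRATCH / "session_main.h5"
TRUTH_CSV = SCRATCH / "session_main_truth.csv"
CORR_CSV = SCRATCH / "correlations_main.csv"
FITS_CSV = SCRATCH / "fits_main.csv"
STATES_CSV = SCRATCH / "states_main.csv"

for _p in (SCRATCH, RESULTS):
    _p.mkdir(exist_ok=True)
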
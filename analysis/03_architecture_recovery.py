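#!/usr/bin/env python
"""Recover fascicle architecture from noiseless phantoms.

Finding: deterministic tracking at SNR infinity recovers fascicle length
essentially exactly (boundary clipping keeps the truncation below one
step), pennation to well under a degree, and PCSA to well inside 10%,
for pennation angles 0, 15 and 30 degrees.
"""

import math
from pathlib import Path

import pandas as pd

from muscledti import io
from muscledti.validation import VALIDATION_ANGLES, slab_recovery

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    rows = [slab_recovery(theta, snr=math.inf, seed=0)
            for theta in VALIDATION_ANGLES]
    df = pd.DataFrame(rows).drop(columns=["snr"])
    io.write_tsv(df, RESULTS / "architecture_recovery_noiseless.tsv")
    cols = ["theta_deg", "n_valid", "n_raw", "length_mm", "length_true_mm",
            "length_err_pct", "pennation_deg", "pennation_err_deg",
            "pcsa_mm2", "pcsa_true_mm2", "pcsa_err_pct"]
    print(df[cols].to_string(index=False))


if __name__ == "__main__":
    main()
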
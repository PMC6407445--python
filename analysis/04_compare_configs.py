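"""Contrasts between lead models and contact configurations.

Reads the sweep output of 03_activation_sweep.py and reports (i) the
per-setting difference between lead models, (ii) the drop in activation
when the long contact 1 of model 3093 is the monopolar cathode, and
(iii) the corresponding bipolar contrast.
"""

from pathlib import Path

import pandas as pd

from snsvta.pipeline import compare_models

SWEEP = Path("results/sweep/activation_synthetic_seed1.csv")


def main():
    if not SWEEP.exists():
        raise SystemExit(f"run analysis/03_activation_sweep.py first ({SWEEP} missing)")
    df = pd.read_csv(SWEEP)
    rep = compare_models(df)
    print("between-model differences (3093 - 3889), percentage points:")
    print(rep["between_models"].to_string(index=False))
    print()
    for model, contrasts in rep["within_model"].items():
        for name, val in contrasts.items():
            print(f"model {model}  {name}: {val:+.1f} points")
    if rep["missing"]:
        print("missing configurations:", rep["missing"])
    out = Path("results/sweep/contrasts.csv")
    rep["between_models"].to_csv(out, index=False)
    print(f"\nwritten to {out}")


if __name__ == "__main__":
    main()
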
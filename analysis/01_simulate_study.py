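#!/usr/bin/env python
"""Generate the synthetic calibration and validation panels.

Writes digestograms, sample metadata and the generating truth under
``data/synthetic/`` for the downstream analysis scripts. The calibration
panel has known clinical GI; the validation panel reuses the same generating
line so predicted eGI can be scored against its (held-out) GI.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from gikit import simulate_calibration_study
from gikit.io import write_digestion_table

ROOT = Path(__file__).resolve().parents[1]


def dump(study, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_digestion_table(study.digestograms, out_dir / "digestograms.csv")
    pd.DataFrame(
        [{"sample_id": m.sample_id, "clinical_gi": m.clinical_gi} for m in study.metas]
    ).to_csv(out_dir / "metadata.csv", index=False)
    truth = {
        "intercept": study.true_intercept,
        "slope": study.true_slope,
        "aucr180": study.true_aucr.tolist(),
        "sk_params": [{"c_inf": c, "k": k} for c, k in study.true_params],
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20240101)
    args = parser.parse_args()

    base = ROOT / "data" / "synthetic"
    calibration = simulate_calibration_study(n_samples=8, seed=args.seed)
    validation = simulate_calibration_study(n_samples=6, seed=args.seed + 1)
    dump(calibration, base / "calibration")
    dump(validation, base / "validation")
    print(f"wrote calibration (8 samples) and validation (6 samples) panels to {base}")


if __name__ == "__main__":
    main()
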
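"""Red-intensity contrast between malignant and benign/normal slides.

Reads the outcomes table produced by 03_run_pipeline.py, summarizes the
per-slide aggregate-region red intensities by reference class, runs the
Mann-Whitney comparison, and flags the slides the consensus misclassified.
Writes results/intensity_contrast.json.
"""

import json
from pathlib import Path

import pandas as pd

from ctsfna.diagnostics import intensity_contrast, outcomes_from_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outcomes_csv = RESULTS / "pipeline_run" / "outcomes.csv"
    if not outcomes_csv.exists():
        raise SystemExit("run analysis/03_run_pipeline.py first")
    outcomes = outcomes_from_frame(pd.read_csv(outcomes_csv))
    res = intensity_contrast(outcomes)
    print(json.dumps(res, indent=1))
    (RESULTS / "intensity_contrast.json").write_text(json.dumps(res, indent=1, sort_keys=True))
    print(f"wrote {RESULTS / 'intensity_contrast.json'}")


if __name__ == "__main__":
    main()
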
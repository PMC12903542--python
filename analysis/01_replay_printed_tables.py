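"""Replay the published cross-tabulations through the metrics engine.

Feeds the packaged per-slide expansion of the published index-vs-reference
table to the confusion-matrix machinery and recomputes every headline
metric, plus the per-category concordance table.  Writes
results/replay_metrics.json.
"""

import json
from pathlib import Path

from ctsfna.data import fig5_category_pairs, load_table2_outcomes
from ctsfna.diagnostics import confusion, outcomes_from_frame, per_category_accuracy

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outcomes = outcomes_from_frame(load_table2_outcomes())
    index = confusion(outcomes)
    comparator = confusion(outcomes, use_comparator=True)
    cats, refs = fig5_category_pairs()
    per_cat = per_category_accuracy(cats, refs)

    print("Index (fluorescence) arm:", index.rounded())
    print("Comparator (PAP-style) arm:", comparator.rounded())
    print(per_cat.to_string(index=False))

    OUT.mkdir(exist_ok=True)
    (OUT / "replay_metrics.json").write_text(
        json.dumps(
            {
                "index": index.as_dict(),
                "comparator": comparator.as_dict(),
                "per_category": per_cat.to_dict(orient="records"),
            },
            indent=1,
            sort_keys=True,
        )
    )
    print(f"\nwrote {OUT / 'replay_metrics.json'}")


if __name__ == "__main__":
    main()
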
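"""Simulated diagnostician panel with majority-rule consensus.

Three blinded readers independently apply the flow chart to each slide.
Reader disagreement is modelled as (a) multiplicative jitter on the
decision thresholds, standing in for individual visual calibration, and
(b) a small residual probability of flipping the final call.  A slide's
panel consensus is positive iff a strict majority of readers call it
positive (for three readers: two or three).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from ctsfna.classify import CtsThresholds, categorize_slide, category_to_call
from ctsfna.images import CellRecord, InputError


@dataclass
class ReaderModel:
    """Stochastic surrogate for one diagnostician.

    ``threshold_jitter`` is the sd of a multiplicative lognormal
    perturbation applied to the geometric thresholds (enlargement,
    circularity cut, link distance); ``flip_prob`` is a residual chance of
    flipping the final binary call.  Both default small; zero gives a
    perfectly rule-following reader.
    """

    reader_id: str = "R1"
    threshold_jitter: float = 0.05
    flip_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_prob < 0.5:
            raise InputError("flip_prob must lie in [0, 0.5)")
        if self.threshold_jitter < 0:
            raise InputError("threshold_jitter must be >= 0")


@dataclass
class PanelCall:
    """Per-reader calls and the majority consensus for one slide."""

    calls: list[str]
    n_positive: int
    consensus: str


def _slide_rng(reader: ReaderModel, slide_id: str) -> np.random.Generator:
    """Deterministic stream keyed by (reader seed, reader id, slide id)."""
    return np.random.default_rng(
        [reader.seed, zlib.crc32(reader.reader_id.encode()), zlib.crc32(slide_id.encode())]
    )


def read_slide(
    cells: list[CellRecord],
    reader: ReaderModel,
    slide_id: str = "",
    thresholds: CtsThresholds | None = None,
) -> str:
    """One reader's binary call on one slide.

    With zero jitter and zero flip probability this is exactly
    ``category_to_call(categorize_slide(cells))``.
    """
    base = thresholds or CtsThresholds()
    rng = _slide_rng(reader, slide_id)
    if reader.threshold_jitter > 0:
        j = reader.threshold_jitter
        jittered = replace(
            base,
            enlargement_um=base.enlargement_um * float(rng.lognormal(0, j)),
            circularity_irregular=min(
                1.0, base.circularity_irregular * float(rng.lognormal(0, j))
            ),
            link_distance_um=base.link_distance_um * float(rng.lognormal(0, j)),
        )
    else:
        # keep the stream aligned so flip draws don't depend on jitter setting
        rng.lognormal(0, 1, size=3)
        jittered = base
    call = category_to_call(categorize_slide(cells, thresholds=jittered))
    if reader.flip_prob > 0 and rng.random() < reader.flip_prob:
        call = "negative" if call == "positive" else "positive"
    return call


def majority_vote(calls: list[str]) -> PanelCall:
    """Combine an odd panel of calls by strict majority."""
    if len(calls) % 2 == 0:
        raise InputError("panel size must be odd (no tie rule is defined)")
    for c in calls:
        if c not in ("positive", "negative"):
            raise InputError(f"unknown call {c!r}")
    n_pos = sum(1 for c in calls if c == "positive")
    consensus = "positive" if n_pos > len(calls) / 2 else "negative"
    return PanelCall(calls=list(calls), n_positive=n_pos, consensus=consensus)


def panel_read(
    cells: list[CellRecord],
    readers: list[ReaderModel],
    slide_id: str = "",
    thresholds: CtsThresholds | None = None,
) -> PanelCall:
    """All readers read one slide; consensus by majority."""
    return majority_vote([read_slide(cells, r, slide_id, thresholds) for r in readers])


def default_panel(seed: int = 0, n_readers: int = 3, **kwargs) -> list[ReaderModel]:
    """A panel of ``n_readers`` readers with distinct substreams."""
    return [
        ReaderModel(reader_id=f"R{i + 1}", seed=(seed + 101 * (i + 1)) % (2**31), **kwargs)
        for i in range(n_readers)
    ]
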
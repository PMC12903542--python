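"""Packaged reference tables (printed cross-tabulations) and their loaders."""

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("ctsfna").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh)


def load_table2_outcomes() -> pd.DataFrame:
    """Per-slide expansion of the published index-vs-reference cross-tabs.

    126 slides with the index (CTS) call, the comparator (PAP-style) level
    and the permanent-section reference.  Within each reference stratum the
    pairing of index and comparator calls is an arbitrary completion
    consistent with both printed marginals (the joint distribution is not
    published); single-test metrics depend only on the marginals.
    """
    return _load("table2_outcomes.csv")


def load_fig5_categories() -> pd.DataFrame:
    """Published per-category counts: category, n_malignant, n_benign_normal."""
    return _load("fig5_categories.csv")


def fig5_category_pairs() -> tuple[list[int], list[str]]:
    """Expand the category counts to per-slide (category, reference) pairs."""
    frame = load_fig5_categories()
    cats: list[int] = []
    refs: list[str] = []
    for r in frame.itertuples():
        cats += [int(r.category)] * (int(r.n_malignant) + int(r.n_benign_normal))
        refs += ["malignant"] * int(r.n_malignant)
        refs += ["benign_normal"] * int(r.n_benign_normal)
    return cats, refs
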
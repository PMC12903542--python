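# ctsfna

Rule-based analysis pipeline for two-channel fluorescence cytology of
breast fine-needle aspirates (FNAB). The assay it models stains the
cytoplasm of oxidative-stress-rich (malignant) cells red with a fluorogenic
acrolein probe and all nuclei blue with Hoechst dye; a slide is called
malignant when it shows an aggregate of **≥ 5 red-stained cells** of which
at least one nucleus is **enlarged (major axis ≥ 10 µm) or irregular in
shape**. The package is for researchers who want to study, stress-test or
extend that rapid-cytology decision rule in silico: it provides a synthetic
smear-image generator with exact ground truth, the full measurement and
classification chain, a simulated three-reader majority panel, and the
diagnostic-accuracy statistics used to evaluate such assays.

## The decision rule

Each slide receives a category from per-cell features:

| category | rule | binary call |
|---|---|---|
| 4 | aggregate of ≥ 5 red cells with ≥ 1 nucleus ≥ 10 µm **or** irregular | positive (malignant) |
| 3 | aggregate(s) of ≥ 5 red cells, all nuclei small and regular | negative |
| 2 | red cells present, no qualifying aggregate | negative |
| 1 | no red-stained epithelial cells | negative |

Features per cell: moment-fit ellipse major/minor axis (µm), circularity
4πA/P² (irregular ⇔ circularity < 0.8), N/C ratio, and the median red
intensity of the cell's red-positive cytoplasm. Aggregation is
single-linkage clustering of red-positive cell centroids at ≤ 25 µm.
A panel of three simulated readers (threshold jitter + residual call flips)
votes; the consensus is positive iff ≥ 2 readers call positive. Accuracy
statistics: sensitivity/specificity/accuracy/PPV/NPV with inadequate slides
excluded from the 2×2 but counted in the insufficiency rate, exact
(binomial) McNemar for paired test comparison, Mann–Whitney U for intensity
contrasts.

## Worked example

```python
from ctsfna.simulate import generate_cohort
from ctsfna.pipeline import process_slide

cohort, slides = generate_cohort(2, 2, 2, seed=7)
for row, (image, truth) in zip(cohort.itertuples(), slides):
    res = process_slide(image)
    print(row.slide_id, row.truth_class, "category", res["category"].value, res["call"])
```

prints

```
S001 malignant category 4 positive
S002 malignant category 4 positive
S003 benign category 3 negative
S004 benign category 3 negative
S005 normal category 1 negative
S006 normal category 1 negative
```

Malignant smears show red aggregates of enlarged nuclei (category 4,
positive); benign smears show weakly red aggregates of small regular nuclei
(category 3, negative); unstained normal smears are category 1.

The numbered drivers under `analysis/` run the full study:
`01_replay_printed_tables.py` (published cross-tab replay),
`02_simulate_cohort.py` (default 63/30/33 cohort and its ground-truth
distributions), `03_run_pipeline.py` (images → cells → categories → panel
consensus → metrics), `04_intensity_contrast.py` (malignant vs
benign/normal red-intensity comparison). Outputs go to `results/`.

A `cts` command exposes the same stages
(`cts sim cohort`, `cts segment`, `cts classify`, `cts evaluate`,
`cts run`, `cts validate`); stages compose through TIFF + CSV + JSON files.

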
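# lungspectra

Spectral (full-spectrum) flow cytometry analysis for highly autofluorescent
murine lung samples: autofluorescence dissection, multi-endmember unmixing,
panel quality control, and hierarchical gating of 17 immune populations.

## The problem

Lung tissue is one of the most autofluorescent tissues a cytometrist can
meet: alveolar macrophages glow across the entire detector array, and that
background makes high-parameter immunophenotyping panels hard to unmix and
hard to gate.  On a 5-laser full-spectrum instrument (64 detectors:
UV 16 / Violet 16 / Blue 14 / Yellow-green 10 / Red 8) every event is a
64-vector, modeled per event as a linear mixture

```
raw ≈ M · a,        M ∈ R^(64×k),  a ∈ R^k
```

where the columns of M are unit-norm *endmember* spectra — 27 fluorochromes
(26 antibodies + a viability dye) plus extra *autofluorescence (AF)
signatures* treated as virtual fluorochromes — and `a` is the per-event
abundance vector, recovered by ordinary least squares.  Including the right
AF endmembers is what makes the difference between clean and smeared
unmixing in lung samples.

The package implements the full computational workflow:

* **spectral core** — detector layouts, signature normalization, the
  similarity index (cosine; 0 = no spectral overlap, 1 = identical spectra)
  and a condition-number complexity index for a panel.
* **synthetic data** — a ground-truth generator for endmember spectra,
  single-stain controls (bead and cell carriers), unstained high-AF
  lung-like samples, and fully stained 17-population samples with
  log-normal expression, shot + electronic detector noise, and
  population-specific scatter.
* **controls** — endmember extraction from single-stain controls, stain
  index, spillover-spreading matrices, and the bead-vs-cell carrier
  decision (lower spread wins; ties go to the higher stain index).
* **AF dissection** — segment an unstained sample into a 7×5 FSC-A×SSC-A
  quantile grid (35 AF candidates), prune near-duplicates keeping the
  brighter signature, and greedily select the minimal AF subset that
  removes unmixing background.
* **unmixing** — QR-based least squares per event (negatives preserved),
  weighted and non-negative variants, and a single-AF vs multi-AF
  comparison report.
* **gating** — the lung hierarchy (debris → singlets → live → CD45+ →
  myeloid/lymphoid branches) as a declarative gate tree resolving 17
  populations, with every threshold derived from reference data rather
  than hard-coded, plus frequency-of-parent tables and recovery metrics.

The fit/transform-shaped stages are scikit-learn estimators
(`SpectralUnmixer`, `AutofluorescenceSelector`, `GateTreeClassifier`) and
compose with sklearn tooling; module-level functions (`unmix_ols`,
`dissect`, `apply_gates`, …) wrap them.

## Worked example

```python
import numpy as np
import lungspectra as ls
from lungspectra.af import AutofluorescenceSelector
from lungspectra.gating import GateTreeClassifier, evaluate_recovery, marker_frame
from lungspectra.unmix import SpectralUnmixer, build_mixing_matrix

panel = ls.default_panel()
profiles = ls.default_lung_profiles()
endmembers = ls.default_endmembers(seed=7)
af_truth = [endmembers[n] for n in endmembers if n not in panel.fluorochromes]

# 1. simulate an unstained lung sample and dissect its autofluorescence
unstained = ls.simulate_unstained(profiles, af_truth, ls.NoiseModel(), 6_000, seed=1)
selector = AutofluorescenceSelector().fit(
    unstained, [endmembers[f] for f in panel.fluorochromes]
)
print("selected AF candidates:", selector.selected_.members)

# 2. simulate a fully stained sample and unmix it (27 fluorochromes + 3 AF)
sample = ls.simulate_sample(
    profiles, np.full(17, 1 / 17), panel, endmembers, ls.NoiseModel(), 20_000, seed=1
)
matrix = build_mixing_matrix(
    [endmembers[f] for f in panel.fluorochromes], selector.selected_
)
result = SpectralUnmixer(endmembers=matrix).fit().unmix(sample)

# 3. gate the unmixed events down the 17-population tree
X = marker_frame(result, sample.scatter, panel)
clf = GateTreeClassifier().fit(X, sample.truth_labels)
gated = clf.gate(X)
print(f"gating accuracy vs truth: {evaluate_recovery(sample.truth_labels, gated.labels).accuracy:.3f}")
```

prints

```
selected AF candidates: ['AF29', 'AF35', 'AF13']
gating accuracy vs truth: 0.965
```

The selector found three scatter-bin AF signatures (ids name the FSC×SSC
bin they came from): one from the alveolar-macrophage corner, one from the
lymphoid region, one from the granulocytic region — matching the three AF
components the generator planted.  Unmixing with them removes the AF
background, and the auto-thresholded gate tree then recovers 96.5% of
events to their true population.  The frequency table in
`gated.frequency_table` reports each gate's event count as a percentage of
its parent gate, the convention used for population statistics.

A full pipeline run (simulate → controls → AF dissection → unmix → gate →
QC, with content-hashed manifests) is available as
`lungspectra run --out <dir> --seed <n>` or `run_pipeline(RunConfig(...))`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch:

* **t1** — the similarity index between a generated spectral signature and
  an identical copy of itself (the upper anchor of the similarity scale);
* **t2** — the number of distinct terminal immune populations the gating
  tree resolves on the standard synthetic lung sample (17 populations,
  equal weights, n = 20,000, default noise), after unmixing with the true
  endmember matrix and deriving all gate thresholds automatically.

Each target is written as `{"value": ..., "n": ...}` to the `--out` JSON.
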
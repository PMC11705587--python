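# Methods

This note documents the models, the synthetic world, the numerical choices,
and the limits of what a green test establishes.

## Signal model

Each event on a 5-laser, 64-detector full-spectrum cytometer is modeled as

    raw = M a + ε,   ε ~ N(0, diag(σ²)),   σ²_d = c_shot · E[raw_d] + σ²_el

where the columns of M are unit-Euclidean-norm endmember spectra
(fluorochromes plus autofluorescence components) and `a` is the per-event
abundance vector.  Unmixing solves the per-event least-squares problem with
a QR-based batch solver (`scipy.linalg.lstsq`, `gelsy`); negative abundances
are preserved, as vendor unmixing does, because clipping would bias
background statistics.  A weighted variant (weights 1/σ²_d) and an NNLS
variant exist behind flags; ordinary least squares is the default and the
documented behavior everywhere.

The *similarity index* between spectra is cosine similarity of the
non-negativity-clamped vectors.  This satisfies the two anchor semantics
the index must have — 0 for spectra with disjoint detector support, 1 for
spectra identical up to positive scale — while the acquisition software's
proprietary formula is unknown.  The *complexity index* of a signature set
is the 2-norm condition number of the column-stacked unit-norm matrix,
computed from its Gram (= similarity) matrix as sqrt(λmax/λmin): 1 for an
orthonormal set, +∞ for a rank-deficient one.  Both are package
definitions, chosen for testability, not reverse-engineered vendor
formulas.

## The synthetic world

The generator is the package's test bed and ships with fixed defaults; a
green test establishes that the *algorithms* behave as specified on data
drawn from this world, not that the world reproduces any real lung.

**Expression levels.** Marker expression is one of {neg, low, pos, hi}
with means one decade apart: 100 / 1,000 / 10,000 / 100,000 instrument
units ("neg" is background binding).  The decade spacing mirrors the
dynamic range real panels are designed for.  The absolute scale is
calibrated so that shot noise at a `pos` population has CV ≈ 1–3% and the
post-unmixing spillover spread is a few percent of a positive signal — the
regime of a real spectral cytometer; the shot coefficient (0.5), electronic
noise SD (1.0) and log-normal expression CV (0.35) are fixed defaults.
Per-event abundances are log-normal with exact mean equal to the level
mean, so the zero-CV configuration is deterministic and the zero-noise
configuration satisfies `raw = M a` exactly (this is asserted to 1e-10).

**Populations.** Seventeen target populations (neutrophils, inflammatory
and resident monocytes, eosinophils, cDC1/cDC2/pDC, alveolar and
interstitial macrophages, B cells, T helper, regulatory and cytotoxic T
cells, NK, ILC1-3) carry the marker phenotypes the gating tree expects
(e.g. Treg = CD3+CD4+CD25+CD127low).  Scatter means/SDs are arbitrary
units chosen so the strata relevant to AF dissection (small/low lymphoid,
high-SSC granulocytes, large/high alveolar macrophages) are separated.
Five percent of cells per population are dead (viability-dye `hi`, truth
label "Dead") to exercise the live gate.

**Autofluorescence.** Three planted AF components: a broad all-laser
"macrophage" component dominated by alveolar macrophages (with smaller
detectable amounts in cDC2 and interstitial macrophages), a UV/violet
component shared by the lymphoid subsets, and a blue/yellow-green component
shared by the granulocytic subsets.  Per-event AF load adds linearly to
SSC-A (slope 0.001 units per AF unit) so that scatter-based dissection sees
the AF structure — the physical premise of the dissection method.  Only the
*ordering* of AF loads is anchored in observation (alveolar macrophages are
by far the most autofluorescent); the numeric weights are package choices.

**Panel.** 27 fluorochromes = 26 antibodies + 1 viability dye.  The
marker→fluorochrome assignment is co-expression aware: spectrally adjacent
channels never pair markers that are bright on, or gated against each
other on, the same cells, and the universally bright CD45/viability/Ly6G
channels sit together buffered by checkpoint markers that are dim
everywhere.  This emulates the iterative panel optimization that real
high-parameter panels undergo; with an adversarial assignment the same
algorithms produce visibly smeared gates, which is realistic but makes the
generator a test of panel design rather than of the pipeline.

**Carriers.** Bead single-stain controls use the reference spectra and no
AF; cell controls add AF background and, for three designated channels
(the PE-Fire810-, APC- and AF700-labeled ones), a deterministic cell-bound
spectral perturbation (a 2-detector roll mixed in at strength 0.35).
Fully stained samples are cellular and share the perturbation, so carrier
comparison should — and does — pick cells for exactly those channels.

## Autofluorescence dissection

`dissect` partitions the unstained sample's FSC-A × SSC-A plane on
per-axis quantile edges (7 × 5 = 35 bins by default; quantiles keep bins
populated for any marginal scatter distribution, though strongly clustered
2-D scatter can still leave a corner bin empty — empty bins are flagged
and dropped).  Bin spectra are per-detector *medians* (bright-cell-outlier
resistant) clamped at zero.  `prune` visits candidates in descending mean
total intensity and keeps a candidate only if its similarity to every kept
one is below 0.98 — "very similar" is not quantified anywhere authoritative;
0.98 sits well above the 0.8 co-expression design guideline and below
exact duplication.  `select` runs greedy forward selection under the
objective *mean absolute unmixed fluorochrome abundance on the unstained
sample* (background bias): a candidate is added only if it improves the
objective by ≥ 5% relative.  The alternative objective — unmixing accuracy
on a fully stained sample — would need truth the real workflow does not
have; background bias on unstained events is the closest scalar the
analyst's visual N×N inspection optimizes.

## Threshold derivation for gating

Gate thresholds are never hard-coded.  Each threshold reference names a
channel and a cut position on the level scale (neg|pos, low|pos, neg|low,
pos|hi).  Derivation mirrors manual gating: the reference strata are the
populations that *reach* the gates using the threshold (computed
symbolically from the profiles' expression levels, with the same
first-matching-child semantics as the event descent), because a gate drawn
on its parent population must tolerate only the spread present there.  The
threshold is the midpoint, in asinh space (cofactor 50), between the
negatives' 99.5th percentile and the positives' histogram mode, mapped
back to data scale.  Special cases: a channel with no negative stratum
anywhere (CD45 in an all-leukocyte sample) backs off two asinh units below
the positive mode; the monocyte SSC-A^low cut is the SSC-A median of the
events in the intermediary-1 gate, resolved per sample at application
time; the singlet gate is a fixed FSC-H/FSC-A ratio cutoff (0.75; singlets
simulate at ≈0.95); the debris cut is placed far below the reference FSC-A
range.  Identical negative and positive distributions are reported as an
unresolvable threshold, and gating refuses to run with unresolved
references.

Events descend the tree taking the first matching child (children are
ordered, conjunction-only predicates); the reported label is the deepest
terminal population on the path (so a CD25+CD127low event inside the
T-helper gate reports "Treg"), sub-state gates (memory T subsets, mature
NK, CD206/CX3CR1 confirmation) annotate without changing the label, and
events failing all children of a branch are "<node>/unassigned".  Dead
cells are excluded from recovery scoring; the live gate is judged by their
absence downstream.

## Numerical choices and degenerate inputs

* All-zero spectra normalize to all-zero (no division by zero) and have
  similarity 0 to everything, which breaks the unit-diagonal convention
  only for that degenerate row.
* The mixing matrix builder rejects duplicate names, near-collinear pairs
  (similarity > 0.999, pair named in the error) and rank-deficient stacks.
* Stain index = (median⁺ − median⁻) / (2 · 1.4826 · MAD⁻); robust
  estimators resist the generator's log-normal tails.  A zero-MAD negative
  yields +∞ with a warning (it happens for blank beads whose clipped noise
  is mostly zeros).
* Spillover spreading is measured on unmixed abundances (entry (f, g) =
  robust SD of g among f-positives minus f-negatives, floored at 0); it is
  asymmetric by nature — the spread lands on the channel whose inference
  depends on the shared detectors.
* Carrier choice is lexicographic: lower total spread wins, with a 5%
  relative band treated as a tie broken by stain index.  The trade-off is
  not formalized anywhere authoritative; this rule makes it deterministic.
* FCS output is float32 (format convention); all computation is float64.

## Known limitations

* The AF spectra are emulated shapes, not digitized instrument spectra;
  the similarity structure of the synthetic panel approximates, but does
  not reproduce, any commercial dye catalog.
* The generator models doublets only through the FSC-H/FSC-A ratio and
  does not model acquisition-time drift, carryover, or per-detector gain
  error.
* Quantile binning guarantees marginal, not joint, bin occupancy.
* The gate tree is the package's operationalization of a manual strategy;
  thresholds derived from truth-labeled references stand in for FMO
  controls, which carry the same information (a negative reference per
  channel) in real experiments.
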
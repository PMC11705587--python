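"""Autofluorescence dissection: scatter-binned AF candidates, near-duplicate
pruning, and greedy selection of the AF endmember subset.

Highly autofluorescent tissues (lung above all, dominated by alveolar
macrophages) leave structured background in every detector.  Treating AF
components as extra "virtual fluorochromes" during unmixing removes that
background — but the components must first be found.  The procedure
implemented here:

1. **dissect** — partition an unstained sample's FSC-A × SSC-A plane into a
   quantile grid (default 7 × 5 = 35 bins) and take each bin's median
   spectrum as an AF candidate (``AF1`` … ``AF35``).
2. **prune** — greedy pass over candidates sorted by descending mean total
   intensity: drop any candidate whose spectrum is very similar
   (similarity ≥ threshold, default 0.98) to an already-kept brighter one.
3. **select** — greedy forward selection of at most ``max_af`` candidates,
   at each step adding the candidate that most reduces the unmixing
   background bias (mean absolute unmixed fluorochrome abundance over the
   unstained events); stop when the relative improvement drops below a
   tolerance (default 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .simulate import EventTable
from .spectral import SpectralSignature, normalize_signature, similarity_index
from .unmix import build_mixing_matrix, unmix_ols

__all__ = [
    "AFCandidate",
    "SelectedAFSet",
    "dissect",
    "prune",
    "select",
    "AutofluorescenceSelector",
]


@dataclass
class AFCandidate:
    """One scatter-bin AF candidate signature."""

    id: str
    bin: tuple[tuple[float, float], tuple[float, float]]  # (FSC-A, SSC-A) intervals
    signature: SpectralSignature
    event_count: int
    mean_total_intensity: float


@dataclass
class SelectedAFSet:
    """The selected AF endmembers plus the full selection trace."""

    members: list[str]
    signatures: list[SpectralSignature]
    selection_trace: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def _quantile_edges(values: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0.0, 1.0, bins + 1))
    edges[0] = -np.inf
    edges[-1] = np.inf
    return edges


def dissect(
    unstained: EventTable,
    grid: tuple[int, int] = (7, 5),
) -> list[AFCandidate]:
    """Segment an unstained sample into scatter-bin AF candidates.

    ``grid`` is (FSC-A columns, SSC-A rows); the default 7 × 5 yields the
    35-signature dissection.  Bin edges are per-axis quantiles so every bin
    is populated for any scatter distribution; every event lands in exactly
    one bin.  Candidates are ordered FSC-major and named ``AF1`` … ``AFn``;
    an empty bin yields an all-zero candidate with ``event_count`` 0,
    flagged for exclusion downstream.
    """
    n_fsc, n_ssc = grid
    if unstained.n_events < 2:
        raise ValueError("need at least 2 events to dissect")
    if unstained.n_events < n_fsc * n_ssc:
        warnings.warn(
            f"only {unstained.n_events} events for {n_fsc * n_ssc} scatter bins"
        )
    fsc = unstained.scatter["FSC-A"].to_numpy()
    ssc = unstained.scatter["SSC-A"].to_numpy()
    fsc_edges = _quantile_edges(fsc, n_fsc)
    ssc_edges = _quantile_edges(ssc, n_ssc)
    fsc_bin = np.clip(np.searchsorted(fsc_edges, fsc, side="right") - 1, 0, n_fsc - 1)
    ssc_bin = np.clip(np.searchsorted(ssc_edges, ssc, side="right") - 1, 0, n_ssc - 1)
    candidates: list[AFCandidate] = []
    k = 0
    for i in range(n_fsc):
        for j in range(n_ssc):
            k += 1
            mask = (fsc_bin == i) & (ssc_bin == j)
            count = int(mask.sum())
            cid = f"AF{k}"
            interval = (
                (float(fsc_edges[i]), float(fsc_edges[i + 1])),
                (float(ssc_edges[j]), float(ssc_edges[j + 1])),
            )
            if count == 0:
                sig = SpectralSignature(cid, np.zeros(unstained.layout.n_detectors), "raw", 0.0)
                candidates.append(AFCandidate(cid, interval, sig, 0, 0.0))
                continue
            med = np.median(unstained.raw[mask], axis=0)
            sig = normalize_signature(med, mode="unit", name=cid, layout=unstained.layout)
            mean_total = float(unstained.raw[mask].sum(axis=1).mean())
            candidates.append(AFCandidate(cid, interval, sig, count, mean_total))
    return candidates


def prune(candidates: Sequence[AFCandidate], threshold: float = 0.98) -> list[AFCandidate]:
    """Drop near-duplicate candidates, keeping the spectrally brighter one.

    Candidates are visited in order of descending mean total intensity
    (ties broken by id for determinism; empty bins dropped first); a
    candidate is kept iff its similarity to every already-kept candidate is
    below ``threshold``.  The output is therefore pairwise-dissimilar and
    independent of input order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    live = [c for c in candidates if c.event_count > 0]
    live.sort(key=lambda c: (-c.mean_total_intensity, c.id))
    kept: list[AFCandidate] = []
    for cand in live:
        if all(
            similarity_index(cand.signature, k.signature) < threshold for k in kept
        ):
            kept.append(cand)
    return kept


def _background_bias(
    unstained: EventTable,
    fluor_endmembers: Sequence[SpectralSignature],
    af_signatures: Sequence[SpectralSignature],
) -> float:
    """Mean absolute unmixed fluorochrome abundance over unstained events."""
    matrix = build_mixing_matrix(list(fluor_endmembers) + list(af_signatures))
    result = unmix_ols(unstained, matrix)
    n_fluor = len(fluor_endmembers)
    return float(np.mean(np.abs(result.abundances[:, :n_fluor])))


def select(
    candidates: Sequence[AFCandidate],
    fluor_endmembers: Sequence[SpectralSignature],
    unstained: EventTable,
    max_af: int = 12,
    tol: float = 0.05,
    collinearity_limit: float = 0.999,
) -> SelectedAFSet:
    """Greedy forward selection of the AF endmember subset.

    Starting from zero AF endmembers, each step adds the candidate whose
    inclusion most reduces the background bias of unmixing the unstained
    sample (candidates that do not pass a relative-improvement tolerance,
    default 5%, stop the search).  Candidates near-collinear with an already
    selected signature are skipped.  The full trace (candidate, objective,
    kept/rejected) is recorded.
    """
    if unstained.n_events == 0:
        raise ValueError("unstained sample is empty")
    pool = [c for c in candidates if c.event_count > 0]
    trace: list[dict] = []
    if not pool:
        return SelectedAFSet([], [], [{"note": "no usable candidates"}])
    selected: list[AFCandidate] = []
    current = _background_bias(unstained, fluor_endmembers, [])
    trace.append({"candidate": None, "objective": current, "kept": True, "note": "baseline"})
    while len(selected) < max_af and pool:
        best: tuple[float, AFCandidate] | None = None
        for cand in pool:
            if any(
                similarity_index(cand.signature, s.signature) > collinearity_limit
                for s in selected
            ):
                continue
            obj = _background_bias(
                unstained,
                fluor_endmembers,
                [s.signature for s in selected] + [cand.signature],
            )
            if best is None or obj < best[0]:
                best = (obj, cand)
        if best is None:
            break
        obj, cand = best
        improvement = (current - obj) / current if current > 0 else 0.0
        if improvement < tol:
            trace.append(
                {"candidate": cand.id, "objective": obj, "kept": False,
                 "note": f"improvement {improvement:.3%} below tolerance"}
            )
            break
        selected.append(cand)
        pool = [c for c in pool if c.id != cand.id]
        trace.append({"candidate": cand.id, "objective": obj, "kept": True})
        current = obj
    return SelectedAFSet(
        members=[c.id for c in selected],
        signatures=[c.signature for c in selected],
        selection_trace=trace,
    )


class AutofluorescenceSelector(BaseEstimator):
    """Scikit-learn style wrapper around dissect → prune → select.

    Parameters
    ----------
    grid : (int, int)
        FSC-A × SSC-A quantile bins (default (7, 5) = 35 candidates).
    prune_threshold : float
        Similarity above which the dimmer of two candidates is dropped.
    max_af : int
        Cap on the number of selected AF endmembers.
    tol : float
        Relative background-bias improvement required to keep adding.

    Attributes (after ``fit``)
    --------------------------
    candidates_ : list of AFCandidate
    pruned_ : list of AFCandidate
    selected_ : SelectedAFSet
    """

    def __init__(
        self,
        grid: tuple[int, int] = (7, 5),
        prune_threshold: float = 0.98,
        max_af: int = 12,
        tol: float = 0.05,
    ):
        self.grid = grid
        self.prune_threshold = prune_threshold
        self.max_af = max_af
        self.tol = tol

    def fit(self, unstained: EventTable, fluor_endmembers: Sequence[SpectralSignature]):
        self.candidates_ = dissect(unstained, self.grid)
        self.pruned_ = prune(self.candidates_, self.prune_threshold)
        self.selected_ = select(
            self.pruned_, fluor_endmembers, unstained, self.max_af, self.tol
        )
        return self
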
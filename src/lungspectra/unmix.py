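"""Per-event linear spectral unmixing against an assembled endmember matrix.

Each event's 64-detector signal is modeled as ``raw ≈ M @ abundance`` where
the columns of M are unit-norm endmember spectra (fluorochromes plus the
selected autofluorescence signatures).  Abundances are recovered by ordinary
least squares (QR-based, the de-facto spectral-cytometry standard); negative
abundances are preserved, matching vendor convention.  A weighted variant
supports per-detector variance models, and a comparison report reproduces
the single-AF versus multi-AF unmixing diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import EventTable, PanelConfig
from .spectral import AURORA_5L, DetectorLayout, SpectralSignature

__all__ = [
    "CollinearityError",
    "EndmemberMatrix",
    "UnmixResult",
    "build_mixing_matrix",
    "unmix_ols",
    "unmix_wls",
    "unmix_nnls",
    "af_comparison_report",
    "SpectralUnmixer",
]


class CollinearityError(ValueError):
    """Raised when two endmember columns are too similar to unmix."""


@dataclass
class EndmemberMatrix:
    """Detector × endmember mixing matrix with unit-norm columns."""

    names: tuple[str, ...]
    matrix: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)
    layout: DetectorLayout = AURORA_5L

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix shape does not match endmember names")

    @property
    def n_endmembers(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "EndmemberMatrix":
        idx = [self.names.index(n) for n in names]
        return EndmemberMatrix(
            tuple(names),
            self.matrix[:, idx],
            {n: self.provenance.get(n, "") for n in names},
            self.layout,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.layout.detector_names), columns=list(self.names)
        )


def build_mixing_matrix(
    panel_signatures: Sequence[SpectralSignature],
    af_set=None,
    layout: DetectorLayout = AURORA_5L,
    provenance: Mapping[str, str] | None = None,
    max_pair_similarity: float = 0.999,
) -> EndmemberMatrix:
    """Assemble fluorochrome + selected-AF signatures into a mixing matrix.

    Columns are unit-normalized; duplicate names are a structural error, and
    near-collinear pairs (similarity > 0.999) or a rank-deficient stack are
    rejected with the offending pair named.  ``af_set`` may be a
    :class:`~lungspectra.af.SelectedAFSet` or a plain signature sequence.
    """
    sigs = list(panel_signatures)
    af_sigs: list[SpectralSignature] = []
    if af_set is not None:
        af_sigs = list(getattr(af_set, "signatures", af_set))
    names = [s.name for s in sigs] + [s.name for s in af_sigs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate endmember names: {dupes}")
    prov = dict(provenance or {})
    for s in af_sigs:
        prov.setdefault(s.name, "af-dissection")
    all_sigs = sigs + af_sigs
    cols = []
    for s in all_sigs:
        if len(s) != layout.n_detectors:
            raise ValueError(f"signature {s.name!r} does not match the layout")
        nrm = np.linalg.norm(s.values)
        if nrm == 0:
            raise ValueError(f"signature {s.name!r} is all-zero")
        cols.append(s.values / nrm)
    mat = np.column_stack(cols)
    worst = (0.0, None)
    for i in range(len(all_sigs)):
        for j in range(i + 1, len(all_sigs)):
            sim = float(mat[:, i] @ mat[:, j])
            if sim > worst[0]:
                worst = (sim, (names[i], names[j]))
            if sim > max_pair_similarity:
                raise CollinearityError(
                    f"endmembers {names[i]!r} and {names[j]!r} are near-collinear "
                    f"(similarity {sim:.6f})"
                )
    sv = np.linalg.svd(mat, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise CollinearityError(
            f"mixing matrix is rank-deficient; most collinear pair: {worst[1]}"
        )
    return EndmemberMatrix(tuple(names), mat, prov, layout)


@dataclass
class UnmixResult:
    """Per-event endmember abundances plus residual diagnostics."""

    abundances: np.ndarray
    endmember_names: tuple[str, ...]
    residual_rms: np.ndarray
    method: str = "ols"

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.endmember_names = tuple(self.endmember_names)
        self.residual_rms = np.asarray(self.residual_rms, dtype=float)
        if self.abundances.shape != (self.residual_rms.size, len(self.endmember_names)):
            raise ValueError("inconsistent unmix result shapes")
        if not np.isfinite(self.abundances).all():
            raise ValueError("abundances must be finite")

    @property
    def n_events(self) -> int:
        return self.abundances.shape[0]

    def of(self, name: str) -> np.ndarray:
        return self.abundances[:, self.endmember_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.abundances, columns=list(self.endmember_names))
        frame["residual_rms"] = self.residual_rms
        return frame


def _event_matrix(events) -> np.ndarray:
    if isinstance(events, EventTable):
        return events.raw
    return np.asarray(events, dtype=float)


def _solve(mat: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sol, *_ = scipy.linalg.lstsq(mat, X.T, lapack_driver="gelsy")
    abund = sol.T
    resid = X - abund @ mat.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return abund, rms


def unmix_ols(events, m: EndmemberMatrix) -> UnmixResult:
    """Ordinary least-squares unmixing of every event.

    Per event the abundance vector minimizes the squared detector residual;
    the residual is orthogonal to the endmember column space (normal
    equations).  Negative abundances are preserved (no clipping).
    """
    X = _event_matrix(events)
    if X.shape[1] != m.matrix.shape[0]:
        raise ValueError(
            f"events have {X.shape[1]} detectors, matrix expects {m.matrix.shape[0]}"
        )
    abund, rms = _solve(m.matrix, X)
    return UnmixResult(abund, m.names, rms, "ols")


def unmix_wls(events, m: EndmemberMatrix, variances) -> UnmixResult:
    """Weighted least squares with per-detector variances (weights 1/var).

    Equal variances reduce exactly to OLS; an infinite variance removes that
    detector from the fit.  Non-positive variances are invalid.
    """
    X = _event_matrix(events)
    var = np.broadcast_to(np.asarray(variances, dtype=float), (m.matrix.shape[0],)).copy()
    if np.any(var <= 0):
        raise ValueError("per-detector variances must be strictly positive")
    w = np.sqrt(1.0 / var)
    w[~np.isfinite(var)] = 0.0  # infinite variance -> detector ignored
    if X.shape[1] != m.matrix.shape[0]:
        raise ValueError("detector dimension mismatch")
    abund, _ = _solve(m.matrix * w[:, None], X * w[None, :])
    resid = X - abund @ m.matrix.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return UnmixResult(abund, m.names, rms, "wls")


def unmix_nnls(events, m: EndmemberMatrix) -> UnmixResult:
    """Non-negative least squares variant (behind a flag; OLS is the default)."""
    X = _event_matrix(events)
    abund = np.empty((X.shape[0], m.n_endmembers))
    for i in range(X.shape[0]):
        abund[i], _ = scipy.optimize.nnls(m.matrix, X[i])
    resid = X - abund @ m.matrix.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return UnmixResult(abund, m.names, rms, "nnls")


def median_align(result: UnmixResult, negative_mask: np.ndarray, channels: Sequence[str]) -> UnmixResult:
    """Optional per-channel shift so a designated negative population's median is 0.

    Off by default in the pipeline; applied channels are recorded in the
    returned result's method tag.
    """
    abund = result.abundances.copy()
    for ch in channels:
        j = result.endmember_names.index(ch)
        abund[:, j] -= np.median(abund[negative_mask, j])
    return UnmixResult(
        abund, result.endmember_names, result.residual_rms,
        result.method + f"+aligned[{','.join(channels)}]",
    )


def af_comparison_report(
    events: EventTable,
    m_multi: EndmemberMatrix,
    m_single: EndmemberMatrix,
    panel: PanelConfig,
    negative_cutoff: float = 300.0,
) -> pd.DataFrame:
    """Single-AF versus multi-AF unmixing comparison on a stained sample.

    For each fluorochrome the report gives the unmixing-induced background
    bias — the mean difference between unmixed and true abundance among
    truth-negative events (events whose true abundance for that fluorochrome
    is at background) — and the spread (robust SD of the unmixed abundances
    among the same events) under both matrices, plus the dominant-laser
    group so improvement can be checked per emission range.
    """
    from .controls import robust_sd

    fluors = [n for n in m_multi.names if n in panel.fluorochromes]
    if set(fluors) != {n for n in m_single.names if n in panel.fluorochromes}:
        raise ValueError("matrices must share their fluorochrome columns")
    if events.truth_abundances is None:
        raise ValueError("comparison needs truth abundances")
    res_multi = unmix_ols(events, m_multi)
    res_single = unmix_ols(events, m_single)
    lasers = events.layout.laser_of_detector
    rows = []
    for f in fluors:
        truth = events.truth_abundance_of(f)
        neg = truth <= negative_cutoff
        if neg.sum() < 10:
            continue
        laser = lasers[int(np.argmax(m_multi.column(f)))]
        bias_m = float(np.mean(res_multi.of(f)[neg] - truth[neg]))
        bias_s = float(np.mean(res_single.of(f)[neg] - truth[neg]))
        rows.append(
            {
                "fluorochrome": f,
                "laser": laser,
                "bias_multi": bias_m,
                "bias_single": bias_s,
                "spread_multi": robust_sd(res_multi.of(f)[neg]),
                "spread_single": robust_sd(res_single.of(f)[neg]),
                "abs_bias_ratio": abs(bias_m) / abs(bias_s) if bias_s != 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)


class SpectralUnmixer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping least-squares unmixing.

    Parameters
    ----------
    endmembers : EndmemberMatrix or sequence of SpectralSignature
        The endmember set; sequences are assembled with
        :func:`build_mixing_matrix` during ``fit``.
    method : {"ols", "wls", "nnls"}
        Solver; ``wls`` requires ``variances``.
    variances : array-like of length n_detectors, optional

    Attributes
    ----------
    matrix_ : EndmemberMatrix
    endmember_names_ : tuple of str
    """

    def __init__(self, endmembers=None, method: str = "ols", variances=None):
        self.endmembers = endmembers
        self.method = method
        self.variances = variances

    def fit(self, X=None, y=None):
        if self.endmembers is None:
            raise ValueError("endmembers must be provided")
        if isinstance(self.endmembers, EndmemberMatrix):
            self.matrix_ = self.endmembers
        else:
            self.matrix_ = build_mixing_matrix(list(self.endmembers))
        if self.method not in {"ols", "wls", "nnls"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "wls" and self.variances is None:
            raise ValueError("wls requires per-detector variances")
        self.endmember_names_ = self.matrix_.names
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "matrix_"):
            self.fit()
        return self.unmix(X).abundances

    def unmix(self, X) -> UnmixResult:
        if not hasattr(self, "matrix_"):
            self.fit()
        if self.method == "ols":
            return unmix_ols(X, self.matrix_)
        if self.method == "nnls":
            return unmix_nnls(X, self.matrix_)
        return unmix_wls(X, self.matrix_, self.variances)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.endmember_names_, dtype=object)
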
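"""Detector layout, spectral signatures, and spectrum-similarity machinery.

Full-spectrum cytometers record every fluorophore's emission across the whole
detector array (64 detectors on a 5-laser Aurora-class instrument) instead of
one bandpass filter per dye.  Everything downstream — control extraction,
autofluorescence dissection, unmixing — manipulates these per-detector
signature vectors, so this module defines the shared representation plus the
two scalar summaries used throughout panel design:

* the *similarity index* between two spectra (0 = no spectral overlap,
  1 = identical shape), implemented as cosine similarity of the non-negative
  signature vectors, and
* the *complexity index* of a signature set, implemented as the 2-norm
  condition number of the column-stacked signature matrix (a direct measure
  of how hard the set is to unmix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectorLayout",
    "AURORA_5L",
    "SpectralSignature",
    "SimilarityMatrix",
    "normalize_signature",
    "similarity_index",
    "similarity_matrix",
    "complexity_index",
]


@dataclass(frozen=True)
class DetectorLayout:
    """Ordered laser → detector-count map defining the detector axis.

    The default is the 5-laser, 64-detector layout (UV16 / V16 / B14 / YG10 /
    R8).  Detector order is fixed and shared by every table in the package.
    """

    lasers: tuple[tuple[str, int], ...] = (
        ("UV", 16),
        ("V", 16),
        ("B", 14),
        ("YG", 10),
        ("R", 8),
    )

    def __post_init__(self) -> None:
        names = self.detector_names
        if len(set(names)) != len(names):
            raise ValueError("detector names must be unique")
        if any(count < 1 for _, count in self.lasers):
            raise ValueError("each laser needs at least one detector")

    @property
    def n_detectors(self) -> int:
        return sum(count for _, count in self.lasers)

    @property
    def detector_names(self) -> tuple[str, ...]:
        return tuple(
            f"{laser}{i}" for laser, count in self.lasers for i in range(1, count + 1)
        )

    @property
    def laser_names(self) -> tuple[str, ...]:
        return tuple(laser for laser, _ in self.lasers)

    @property
    def laser_of_detector(self) -> tuple[str, ...]:
        """Laser label for each detector index."""
        return tuple(laser for laser, count in self.lasers for _ in range(count))

    def laser_slice(self, laser: str) -> slice:
        start = 0
        for name, count in self.lasers:
            if name == laser:
                return slice(start, start + count)
            start += count
        raise KeyError(f"unknown laser {laser!r}")


#: The shipped default: Cytek Aurora 5-laser 64-detector layout.
AURORA_5L = DetectorLayout()


@dataclass
class SpectralSignature:
    """One endmember's intensity profile across the detector array.

    ``values`` is non-negative (background subtraction is clamped at zero);
    ``peak_intensity`` retains the pre-normalization maximum so brightness
    comparisons survive normalization.
    """

    name: str
    values: np.ndarray
    normalization: str = "raw"  # one of {"peak", "unit", "raw"}
    peak_intensity: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signature values must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValueError("signature values must be non-negative")
        if self.normalization not in {"peak", "unit", "raw"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def __len__(self) -> int:
        return self.values.size

    def as_unit(self) -> "SpectralSignature":
        """Return a unit-Euclidean-norm copy (the similarity convention)."""
        nrm = float(np.linalg.norm(self.values))
        if nrm == 0.0:
            return SpectralSignature(self.name, self.values.copy(), "unit", self.peak_intensity)
        return SpectralSignature(self.name, self.values / nrm, "unit", self.peak_intensity)


def normalize_signature(
    raw: Sequence[float] | np.ndarray,
    mode: str = "peak",
    name: str = "",
    layout: DetectorLayout | None = None,
) -> SpectralSignature:
    """Clamp a raw (background-subtracted) spectrum and normalize it.

    Negative entries are clamped to zero *before* normalization; non-finite
    entries are treated as missing background-subtraction artifacts and set
    to zero (an all-NaN input is rejected).  ``peak`` mode divides by the
    maximum, ``unit`` by the Euclidean norm, ``raw`` leaves values as-is.
    The pre-normalization maximum is recorded as ``peak_intensity``.  An
    all-zero spectrum is returned unchanged (no division by zero).
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1:
        raise ValueError("raw spectrum must be a 1-D vector")
    if layout is not None and arr.size != layout.n_detectors:
        raise ValueError(
            f"spectrum length {arr.size} does not match layout ({layout.n_detectors} detectors)"
        )
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("spectrum has no finite values")
    arr = np.where(finite, arr, 0.0)
    arr = np.clip(arr, 0.0, None)
    peak = float(arr.max())
    if mode == "peak":
        values = arr / peak if peak > 0 else arr
    elif mode == "unit":
        nrm = float(np.linalg.norm(arr))
        values = arr / nrm if nrm > 0 else arr
    elif mode == "raw":
        values = arr
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return SpectralSignature(name=name, values=values, normalization=mode, peak_intensity=peak)


def _vector_of(sig) -> np.ndarray:
    if isinstance(sig, SpectralSignature):
        return sig.values
    return np.clip(np.asarray(sig, dtype=float), 0.0, None)


def similarity_index(a, b) -> float:
    """Cosine similarity of two non-negative spectra, in [0, 1].

    0 means the spectra have disjoint detector support (no spectral
    overlap); 1 means they are identical up to a positive scale.  If either
    spectrum is all-zero the index is defined as 0.
    """
    va, vb = _vector_of(a), _vector_of(b)
    if va.size != vb.size:
        raise ValueError(f"layout mismatch: {va.size} vs {vb.size} detectors")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(va, vb) / (na * nb), 0.0, 1.0))


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise similarity indices with stable ordering."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(tuple(frame.index), frame.to_numpy(dtype=float))

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])


def similarity_matrix(signatures: Iterable[SpectralSignature]) -> SimilarityMatrix:
    """N×N similarity comparison of a signature set.

    Entry (i, j) equals ``similarity_index(signatures[i], signatures[j])``;
    the vectorized Gram-matrix computation matches the pairwise loop to
    floating-point round-off.
    """
    sigs = list(signatures)
    if not sigs:
        raise ValueError("need at least one signature")
    mat = np.stack([_vector_of(s) for s in sigs])
    if len({v.size for v in mat}) > 1:  # pragma: no cover - stack already enforces
        raise ValueError("signatures do not share a layout")
    norms = np.linalg.norm(mat, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = mat / safe[:, None]
    gram = np.clip(unit @ unit.T, 0.0, 1.0)
    nonzero = norms > 0
    diag = np.where(nonzero, 1.0, 0.0)
    np.fill_diagonal(gram, diag)
    gram[~nonzero, :] = 0.0
    gram[:, ~nonzero] = 0.0
    np.fill_diagonal(gram, diag)
    gram = 0.5 * (gram + gram.T)
    names = tuple(getattr(s, "name", f"S{i}") or f"S{i}" for i, s in enumerate(sigs))
    return SimilarityMatrix(names=names, values=gram)


def complexity_index(m: SimilarityMatrix | np.ndarray) -> float:
    """Panel entanglement summary: condition number of the signature set.

    For unit-norm signature columns S the similarity matrix is the Gram
    matrix G = SᵀS, so the 2-norm condition number of S is
    sqrt(λmax(G) / λmin(G)).  Orthonormal endmembers give 1; a rank-deficient
    set (e.g. two identical signatures) gives +infinity.
    """
    values = m.values if isinstance(m, SimilarityMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("similarity matrix must be square")
    eig = np.linalg.eigvalsh(0.5 * (values + values.T))
    lam_max = float(eig[-1])
    lam_min = float(eig[0])
    if lam_max <= 0:
        return float("inf")
    if lam_min <= lam_max * 1e-12:
        return float("inf")
    return float(np.sqrt(lam_max / lam_min))
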
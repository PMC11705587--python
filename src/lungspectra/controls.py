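"""Single-stain control processing: signature extraction, stain index,
spillover-spreading, and the bead-vs-cell unmixing carrier decision.

A single-stain control carries one antibody-fluorochrome conjugate on a bead
or cell carrier.  The control's endmember spectrum is extracted as the median
spectrum of the brightest events minus the median unstained spectrum.  Panel
quality is summarized by the stain index (positive/negative separation
normalized by the negative spread) and a spillover-spreading matrix computed
on unmixed abundances; per fluorochrome, the carrier whose endmember yields
lower total spread wins (ties broken by higher stain index), mirroring the
"reduced spread and higher signal intensity" rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import EventTable, NoiseModel, PanelConfig, simulate_blank
from .spectral import SpectralSignature, normalize_signature

__all__ = [
    "QCReport",
    "extract_signature",
    "stain_index",
    "robust_sd",
    "spread_matrix",
    "choose_carrier",
    "carrier_qc",
]


def robust_sd(values: np.ndarray) -> float:
    """Outlier-resistant spread estimate: 1.4826 × median absolute deviation."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


@dataclass
class QCReport:
    """Panel QC summary for one unmixing carrier."""

    carrier: str
    stain_indices: dict[str, float]
    spread: pd.DataFrame
    carrier_choice: dict[str, str] | None = None
    notes: list[str] = field(default_factory=list)

    def total_spread(self, fluor: str) -> float:
        """Total spillover spreading caused by `fluor` on all other channels."""
        return float(self.spread.loc[fluor].sum())


def extract_signature(
    control: EventTable,
    unstained: EventTable,
    positive_fraction: float = 0.25,
    name: str = "",
) -> SpectralSignature:
    """Extract an endmember spectrum from a single-stain control.

    Positive events are the top ``positive_fraction`` by the control's
    brightest detector; the signature is the per-detector median of those
    events minus the median unstained spectrum, clamped at zero and
    unit-normalized.  ``peak_intensity`` keeps the pre-normalization maximum
    for brightness (carrier) comparisons.
    """
    if control.n_events < 100:
        raise ValueError(
            f"control has only {control.n_events} events; need at least 100"
        )
    if not 0.0 < positive_fraction <= 0.5:
        raise ValueError("positive_fraction must lie in (0, 0.5]")
    brightest = int(np.argmax(control.raw.mean(axis=0)))
    order = np.argsort(control.raw[:, brightest])
    n_pos = max(int(round(positive_fraction * control.n_events)), 1)
    pos = control.raw[order[-n_pos:]]
    diff = np.median(pos, axis=0) - np.median(unstained.raw, axis=0)
    # a control indistinguishable from unstained has no signature: flag as all-zero
    noise_floor = max(5.0 * float(np.std(unstained.raw)), 1e-12)
    if float(np.max(diff)) < noise_floor:
        zero = np.zeros(control.raw.shape[1])
        return SpectralSignature(name=name, values=zero, normalization="unit", peak_intensity=0.0)
    return normalize_signature(diff, mode="unit", name=name, layout=control.layout)


def stain_index(positive: Sequence[float], negative: Sequence[float]) -> float:
    """Separation of a stained positive from its negative population.

    (median(positive) − median(negative)) / (2 × robust SD(negative)); the
    robust SD is 1.4826 × MAD.  A degenerate zero-spread negative yields
    +infinity with a warning.
    """
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    if positive.size < 10 or negative.size < 10:
        raise ValueError("stain index needs at least 10 values per population")
    sd = robust_sd(negative)
    delta = float(np.median(positive) - np.median(negative))
    if sd == 0.0:
        warnings.warn("negative population has zero robust SD; stain index is infinite")
        return float("inf")
    return delta / (2.0 * sd)


def _split_positive(abund: np.ndarray) -> np.ndarray:
    """Boolean positive mask from a control's own-channel abundances."""
    lo, hi = np.quantile(abund, [0.1, 0.9])
    return abund > 0.5 * (lo + hi)


def spread_matrix(unmixed_controls: Mapping[str, "UnmixResult"]) -> pd.DataFrame:
    """Spillover-spreading matrix at the unmixed-abundance level.

    Entry (f, g), f ≠ g, is the robust SD of endmember-g abundances among
    f-positive events minus that among f-negative events, floored at zero;
    the diagonal is identically zero.  Zero-noise controls give the zero
    matrix.
    """
    fluors = list(unmixed_controls)
    mat = pd.DataFrame(0.0, index=fluors, columns=fluors)
    for f in fluors:
        res = unmixed_controls[f]
        if f not in res.endmember_names:
            raise KeyError(f"control {f!r} was not unmixed against its own endmember")
        own = res.abundances[:, res.endmember_names.index(f)]
        pos = _split_positive(own)
        if pos.sum() == 0 or (~pos).sum() == 0:
            continue
        for g in fluors:
            if g == f or g not in res.endmember_names:
                continue
            other = res.abundances[:, res.endmember_names.index(g)]
            delta = robust_sd(other[pos]) - robust_sd(other[~pos])
            mat.loc[f, g] = max(delta, 0.0)
    return mat


def choose_carrier(
    bead_qc: QCReport,
    cell_qc: QCReport,
    rel_tol: float = 0.05,
) -> dict[str, str]:
    """Pick the unmixing carrier per fluorochrome.

    Lexicographic rule: the carrier with lower total spread contribution
    wins; spreads equal within ``rel_tol`` (relative) are a tie, broken by
    the higher stain index.  Decisions and both metric values are logged on
    both reports.
    """
    fluors = set(bead_qc.stain_indices)
    if fluors != set(cell_qc.stain_indices):
        raise ValueError("bead and cell QC reports cover different fluorochromes")
    choice: dict[str, str] = {}
    for f in bead_qc.stain_indices:
        sb, sc = bead_qc.total_spread(f), cell_qc.total_spread(f)
        tied = abs(sb - sc) <= rel_tol * max(sb, sc, 1e-12)
        if tied:
            carrier = "cells" if cell_qc.stain_indices[f] > bead_qc.stain_indices[f] else "beads"
            reason = "spread tie; higher stain index"
        else:
            carrier = "beads" if sb < sc else "cells"
            reason = "lower spread"
        choice[f] = carrier
        note = (
            f"{f}: spread beads={sb:.4g} cells={sc:.4g}; "
            f"stain index beads={bead_qc.stain_indices[f]:.4g} "
            f"cells={cell_qc.stain_indices[f]:.4g} -> {carrier} ({reason})"
        )
        bead_qc.notes.append(note)
        cell_qc.notes.append(note)
    bead_qc.carrier_choice = choice
    cell_qc.carrier_choice = choice
    return choice


def carrier_qc(
    bead_controls: Mapping[str, EventTable],
    cell_controls: Mapping[str, EventTable],
    panel: PanelConfig,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    positive_fraction: float = 0.25,
    af_endmembers: Sequence[SpectralSignature] = (),
) -> tuple[QCReport, QCReport, dict[str, SpectralSignature], dict[str, SpectralSignature]]:
    """Build bead and cell QC reports for the carrier decision.

    Endmember spectra are extracted from each carrier's own controls (against
    a matching unstained carrier), and stain indices come from each carrier's
    own brightest-detector distributions.  Spread, however, is evaluated on
    the *cell* control events under both candidate endmember matrices — the
    real sample is cellular, so a bead spectrum that no longer matches the
    cell-bound conjugate shows up as spillover spreading there.
    """
    from .unmix import build_mixing_matrix, unmix_ols

    blank_beads = simulate_blank(noise=noise, seed=seed, carrier="beads")
    blank_cells = simulate_blank(
        noise=noise, seed=seed + 1, carrier="cells", af_endmembers=af_endmembers
    )
    bead_sigs: dict[str, SpectralSignature] = {}
    cell_sigs: dict[str, SpectralSignature] = {}
    stain_b: dict[str, float] = {}
    stain_c: dict[str, float] = {}
    for f in panel.fluorochromes:
        bead_sigs[f] = extract_signature(
            bead_controls[f], blank_beads, positive_fraction, name=f
        )
        cell_sigs[f] = extract_signature(
            cell_controls[f], blank_cells, positive_fraction, name=f
        )
        for controls, out in ((bead_controls, stain_b), (cell_controls, stain_c)):
            tbl = controls[f]
            brightest = int(np.argmax(tbl.raw.mean(axis=0)))
            vals = tbl.raw[:, brightest]
            order = np.argsort(vals)
            n_pos = max(int(round(positive_fraction * tbl.n_events)), 10)
            out[f] = stain_index(vals[order[-n_pos:]], vals[order[:n_pos]])

    af_list = list(af_endmembers)
    m_bead = build_mixing_matrix(list(bead_sigs.values()) + af_list)
    m_cell = build_mixing_matrix(list(cell_sigs.values()) + af_list)
    unmixed_b = {f: unmix_ols(cell_controls[f], m_bead) for f in panel.fluorochromes}
    unmixed_c = {f: unmix_ols(cell_controls[f], m_cell) for f in panel.fluorochromes}
    bead_qc = QCReport("beads", stain_b, spread_matrix(unmixed_b))
    cell_qc = QCReport("cells", stain_c, spread_matrix(unmixed_c))
    return bead_qc, cell_qc, bead_sigs, cell_sigs
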
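"""Synthetic full-spectrum cytometry data with ground truth.

Everything the pipeline consumes can be generated here: fluorochrome and
autofluorescence (AF) endmember spectra over the 64-detector layout,
single-stain controls on bead or cell carriers, unstained high-AF lung-like
samples, and fully stained multi-population samples with per-event truth
labels and truth abundances.

The stated world
----------------
* 27 fluorochromes (26 antibodies + 1 viability dye) and 3 AF endmembers by
  default (30 unmixing parameters in the full configuration).
* 17 target immune populations with marker expression encoded as one of
  {neg, low, pos, hi}; the expression means are decades apart
  (background, then 10x / 100x / 1000x background, with background at 100
  instrument units), mirroring typical cytometry dynamic range.
* Per-event expression varies log-normally (default CV 0.35); detector noise
  is signal-proportional shot noise (Gaussian approximation of the Poisson
  limit, variance = shot_coefficient × mean signal) plus constant Gaussian
  electronic noise.
* Autofluorescence composition follows the scatter structure, as in real
  lung: the broad all-laser "macrophage" AF component is dominated by
  alveolar macrophages (so its dissected signature matches pure AMO AF),
  with smaller detectable amounts in cDC2 and interstitial macrophages; a
  UV/violet-weighted component spreads across the lymphoid subsets and a
  blue/yellow-green component across the granulocytic/myeloid subsets.
  Per-event AF load is linearly linked to SSC-A so that scatter-based AF
  dissection is meaningful.
* A configurable fraction of dead (viability-dye-positive) cells (default
  5%) exercises the live gate; their truth label is ``"Dead"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral import AURORA_5L, DetectorLayout, SpectralSignature

__all__ = [
    "LEVELS",
    "CELL_SHIFTED_DEFAULT",
    "AF_TRUTH_NAMES",
    "PanelConfig",
    "PopulationProfile",
    "NoiseModel",
    "EventTable",
    "default_panel",
    "default_lung_profiles",
    "make_endmember_spectra",
    "default_endmembers",
    "cell_variant",
    "simulate_sample",
    "simulate_unstained",
    "simulate_blank",
    "simulate_single_stain_controls",
]

#: Expression-level means in instrument units: neg = background (100), then decades.
LEVELS: dict[str, float] = {"neg": 100.0, "low": 1_000.0, "pos": 10_000.0, "hi": 100_000.0}

#: Fluorochromes whose spectrum shifts when conjugated antibody binds cells
#: instead of beads (the channels where cell carriers improve unmixing).
CELL_SHIFTED_DEFAULT: tuple[str, ...] = ("PE-Fire810", "APC", "AF700")

#: Names of the three planted AF endmembers (ground truth, before dissection
#: renames candidates AF1..AF35 by scatter bin).
AF_TRUTH_NAMES: tuple[str, ...] = ("AF-mac", "AF-lymph", "AF-gran")

DEAD_LABEL = "Dead"

#: Linear link between a cell's total AF abundance and its SSC-A.
SSC_AF_SLOPE = 0.001


@dataclass(frozen=True)
class PanelConfig:
    """Marker ↔ fluorochrome map for the antibody panel.

    ``entries`` pairs each marker with its fluorochrome; the viability dye is
    one entry (marker "Viability") and is also named by
    ``viability_channel``.  ``af_names`` lists AF signatures included as
    virtual fluorochromes after AF selection.
    """

    entries: tuple[tuple[str, str], ...]
    viability_channel: str
    af_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        fluors = [f for _, f in self.entries]
        if len(set(fluors)) != len(fluors):
            raise ValueError("fluorochrome names must be unique")
        if self.viability_channel not in fluors:
            raise ValueError("viability channel must appear in the panel entries")

    @property
    def fluorochromes(self) -> tuple[str, ...]:
        return tuple(f for _, f in self.entries)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.entries)

    @property
    def antibody_markers(self) -> tuple[str, ...]:
        return tuple(m for m, f in self.entries if f != self.viability_channel)

    def fluor_of(self, marker: str) -> str:
        for m, f in self.entries:
            if m == marker:
                return f
        raise KeyError(f"marker {marker!r} not in panel")

    def marker_of(self, fluor: str) -> str:
        for m, f in self.entries:
            if f == fluor:
                return m
        raise KeyError(f"fluorochrome {fluor!r} not in panel")

    def with_af(self, af_names: Sequence[str]) -> "PanelConfig":
        return replace(self, af_names=tuple(af_names))


# Entry order fixes each fluorochrome's spectral position (dominant detectors
# run across the array in panel order).  The marker assignment is
# co-expression aware, the way an optimized panel is built: spectrally
# adjacent channels never pair markers that are bright on, or gated against
# each other on, the same cells; the universally bright CD45/viability/Ly6G
# channels sit together (their gates tolerate mutual spread) buffered by
# checkpoint/maturation markers that are dim on every population.
_DEFAULT_PANEL_ENTRIES: tuple[tuple[str, str], ...] = (
    ("PD-1", "BUV395"),
    ("CD45", "BUV496"),
    ("Viability", "Zombie UV"),
    ("Ly6G", "BUV563"),
    ("CD19", "BUV661"),
    ("CD64", "BUV737"),
    ("CD3", "BUV805"),
    ("CD24", "eFluor450"),
    ("CD4", "BV510"),
    ("MHCII", "BV570"),
    ("CD8", "BV605"),
    ("Ly6C", "BV650"),
    ("CD127", "BV711"),
    ("CD206", "BV785"),
    ("CD11c", "FITC"),
    ("PD-L1", "Spark Blue 550"),
    ("CD11b", "PerCP-Cy5.5"),
    ("CX3CR1", "PE"),
    ("CD25", "PE-Dazzle594"),
    ("CD103", "PE-Cy5"),
    ("KLRG1", "PE-Cy7"),
    ("CD44", "PE-Fire810"),
    ("CD335", "APC"),
    ("CD122", "R718"),
    ("CD62L", "AF700"),
    ("CD69", "APC-Cy7"),
    ("CTLA-4", "APC-Fire750"),
)


def default_panel(af_names: Sequence[str] = ()) -> PanelConfig:
    """The default 27-fluorochrome panel (26 antibodies + viability dye)."""
    return PanelConfig(
        entries=_DEFAULT_PANEL_ENTRIES,
        viability_channel="Zombie UV",
        af_names=tuple(af_names),
    )


@dataclass(frozen=True)
class PopulationProfile:
    """Marker expression, AF load, scatter, and viability of one population."""

    name: str
    marker_levels: Mapping[str, str]
    af_weights: Mapping[str, float] = field(default_factory=dict)
    scatter: tuple[float, float, float, float] = (100.0, 10.0, 60.0, 8.0)
    viability: float = 0.95

    def __post_init__(self) -> None:
        for marker, level in self.marker_levels.items():
            if level not in LEVELS:
                raise ValueError(f"{self.name}: unknown level {level!r} for {marker}")
        if any(w < 0 for w in self.af_weights.values()):
            raise ValueError(f"{self.name}: AF weights must be non-negative")
        fsc_mean, fsc_sd, ssc_mean, ssc_sd = self.scatter
        if fsc_sd <= 0 or ssc_sd <= 0:
            raise ValueError(f"{self.name}: scatter SDs must be positive")
        if not 0.0 <= self.viability <= 1.0:
            raise ValueError(f"{self.name}: viability must lie in [0, 1]")

    def level_of(self, marker: str) -> str:
        return self.marker_levels.get(marker, "neg")


@dataclass(frozen=True)
class NoiseModel:
    """Detector- and expression-noise parameters.

    ``shot_coefficient`` scales signal-proportional Gaussian shot noise
    (variance = coefficient × mean signal), ``electronic_sd`` is the additive
    per-detector Gaussian noise, ``abundance_cv`` the log-normal CV of
    per-event expression.  The all-zero model is exactly deterministic.
    """

    shot_coefficient: float = 0.5
    electronic_sd: float = 1.0
    abundance_cv: float = 0.35

    def __post_init__(self) -> None:
        if min(self.shot_coefficient, self.electronic_sd, self.abundance_cv) < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def is_zero(self) -> bool:
        return (
            self.shot_coefficient == 0.0
            and self.electronic_sd == 0.0
            and self.abundance_cv == 0.0
        )


@dataclass
class EventTable:
    """Per-event raw detector intensities plus scatter and optional truth."""

    raw: np.ndarray
    scatter: pd.DataFrame
    layout: DetectorLayout = AURORA_5L
    truth_labels: np.ndarray | None = None
    truth_abundances: np.ndarray | None = None
    truth_names: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2:
            raise ValueError("raw must be an events × detectors matrix")
        if self.raw.shape[1] != self.layout.n_detectors:
            raise ValueError(
                f"raw has {self.raw.shape[1]} detectors, layout expects {self.layout.n_detectors}"
            )
        for col in ("FSC-A", "SSC-A", "FSC-H"):
            if col not in self.scatter.columns:
                raise ValueError(f"scatter is missing column {col!r}")
        n = self.raw.shape[0]
        if len(self.scatter) != n:
            raise ValueError("scatter row count does not match raw")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels, dtype=object)
            if self.truth_labels.shape[0] != n:
                raise ValueError("truth labels length mismatch")
        if self.truth_abundances is not None:
            self.truth_abundances = np.asarray(self.truth_abundances, dtype=float)
            if self.truth_abundances.shape[0] != n:
                raise ValueError("truth abundance row count mismatch")
            if self.truth_names is not None and self.truth_abundances.shape[1] != len(
                self.truth_names
            ):
                raise ValueError("truth abundance column count mismatch")

    @property
    def n_events(self) -> int:
        return self.raw.shape[0]

    def truth_abundance_of(self, name: str) -> np.ndarray:
        if self.truth_abundances is None or self.truth_names is None:
            raise ValueError("event table carries no truth abundances")
        return self.truth_abundances[:, self.truth_names.index(name)]


# --------------------------------------------------------------------------
# Endmember spectra
# --------------------------------------------------------------------------


def _emission_hump(positions: np.ndarray, center: float, width: float) -> np.ndarray:
    """Asymmetric (red-tailed) emission-like hump over detector positions."""
    z = (positions - center) / width
    return np.where(z < 0, np.exp(-0.5 * z**2), np.exp(-0.5 * (z / 1.8) ** 2))


def _fluor_spectrum(rng: np.random.Generator, layout: DetectorLayout, dominant: int) -> np.ndarray:
    """A smooth unimodal-per-laser fluorochrome spectrum peaking at `dominant`."""
    n = layout.n_detectors
    values = np.zeros(n)
    positions = np.arange(n, dtype=float)
    # position of the dominant detector within its laser, reused across lasers
    start = 0
    dom_laser = 0
    frac = 0.0
    for i, (_, count) in enumerate(layout.lasers):
        if start <= dominant < start + count:
            dom_laser = i
            frac = (dominant - start) / max(count - 1, 1)
            break
        start += count
    start = 0
    for i, (_, count) in enumerate(layout.lasers):
        center = start + frac * (count - 1) + rng.normal(0.0, 0.3)
        width = rng.uniform(1.0, 2.2)
        if i == dom_laser:
            amp = 1.0
        else:
            amp = rng.uniform(0.02, 0.35) / (1 + abs(i - dom_laser))
        seg = slice(start, start + count)
        values[seg] += amp * _emission_hump(positions[seg], center, width)
        start += count
    return values


_AF_LASER_AMPS = {
    # broad multi-laser humps; first component is the all-laser macrophage AF
    0: (1.0, 0.9, 0.8, 0.7, 0.6),
    1: (1.0, 0.7, 0.2, 0.05, 0.02),
    2: (0.15, 0.35, 1.0, 0.8, 0.3),
}


def _af_spectrum(rng: np.random.Generator, layout: DetectorLayout, index: int) -> np.ndarray:
    n = layout.n_detectors
    values = np.full(n, 0.02)
    positions = np.arange(n, dtype=float)
    amps = _AF_LASER_AMPS.get(index % 3, (0.5,) * len(layout.lasers))
    start = 0
    for i, (_, count) in enumerate(layout.lasers):
        amp = amps[i % len(amps)] * rng.uniform(0.85, 1.15)
        center = start + rng.uniform(0.25, 0.75) * (count - 1)
        width = rng.uniform(4.0, 8.0)
        seg = slice(start, start + count)
        values[seg] += amp * np.exp(-0.5 * ((positions[seg] - center) / width) ** 2)
        start += count
    return values


def make_endmember_spectra(
    n_fluorochromes: int,
    n_af: int,
    layout: DetectorLayout = AURORA_5L,
    seed: int = 0,
    max_similarity: float = 0.95,
    max_tries: int = 60,
) -> list[SpectralSignature]:
    """Generate distinct fluorochrome + AF endmember spectra.

    Fluorochromes are smooth unimodal-per-laser peaks with distinct dominant
    detectors (pairwise similarity < ``max_similarity`` enforced by retry);
    AF spectra are broad multi-laser humps.  Deterministic per seed.
    """
    if n_fluorochromes < 1 and n_af < 1:
        raise ValueError("need at least one endmember")
    n = layout.n_detectors
    if n_fluorochromes > n:
        raise ValueError(
            f"cannot place {n_fluorochromes} distinct peaks in a {n}-detector layout"
        )
    rng = np.random.default_rng(seed)
    dominants = np.unique(np.round(np.linspace(0, n - 1, max(n_fluorochromes, 1))).astype(int))
    while dominants.size < n_fluorochromes:  # fill collisions from rounding
        pool = np.setdiff1d(np.arange(n), dominants)
        dominants = np.sort(np.append(dominants, pool[0]))
    sigs: list[SpectralSignature] = []
    for i in range(n_fluorochromes):
        for attempt in range(max_tries):
            vals = _fluor_spectrum(rng, layout, int(dominants[i]))
            vals = vals / np.linalg.norm(vals)
            if all(float(vals @ s.values) < max_similarity for s in sigs):
                sigs.append(
                    SpectralSignature(f"F{i + 1:02d}", vals, "unit", float(vals.max()))
                )
                break
        else:
            raise ValueError(
                f"could not place fluorochrome {i + 1} below similarity {max_similarity}"
            )
    for j in range(n_af):
        vals = _af_spectrum(rng, layout, j)
        vals = vals / np.linalg.norm(vals)
        name = AF_TRUTH_NAMES[j] if j < len(AF_TRUTH_NAMES) else f"AF-x{j + 1}"
        sigs.append(SpectralSignature(name, vals, "unit", float(vals.max())))
    return sigs


def default_endmembers(
    seed: int = 7, layout: DetectorLayout = AURORA_5L
) -> dict[str, SpectralSignature]:
    """27 panel fluorochrome spectra + 3 AF truth spectra, keyed by name."""
    panel = default_panel()
    sigs = make_endmember_spectra(len(panel.fluorochromes), 3, layout=layout, seed=seed)
    out: dict[str, SpectralSignature] = {}
    for fluor, sig in zip(panel.fluorochromes, sigs[: len(panel.fluorochromes)]):
        out[fluor] = SpectralSignature(fluor, sig.values, "unit", sig.peak_intensity)
    for sig in sigs[len(panel.fluorochromes):]:
        out[sig.name] = sig
    return out


def cell_variant(sig: SpectralSignature, strength: float = 0.35) -> SpectralSignature:
    """Deterministic cell-bound spectral perturbation of a fluorochrome.

    Models the red-shift/broadening some conjugates show on cells versus
    beads by mixing the spectrum with a two-detector roll of itself.
    """
    shifted = np.roll(sig.values, 2)
    vals = (1.0 - strength) * sig.values + strength * shifted
    vals = vals / np.linalg.norm(vals)
    return SpectralSignature(sig.name, vals, "unit", sig.peak_intensity)


# --------------------------------------------------------------------------
# Population profiles
# --------------------------------------------------------------------------

_COMMON = {"CD45": "pos"}


def _profile(name, levels, af, scatter, viability=0.95):
    return PopulationProfile(
        name=name,
        marker_levels={**_COMMON, **levels},
        af_weights=af,
        scatter=scatter,
        viability=viability,
    )


def default_lung_profiles() -> list[PopulationProfile]:
    """The 17 target lung immune populations and their gating phenotypes.

    Marker levels follow the hierarchical gating logic (see
    :mod:`lungspectra.gating`): e.g. Tregs are CD3+CD4+CD25+CD127low,
    alveolar macrophages are CD64+CD11c+CD206+ with the highest AF load.
    Scatter means/SDs are in arbitrary instrument units chosen so that the
    scatter strata used for AF dissection (lymphoid low/low, granulocyte
    high-SSC, alveolar macrophage high/high) are well separated.
    """
    mac = AF_TRUTH_NAMES[0]
    lym = AF_TRUTH_NAMES[1]
    gran = AF_TRUTH_NAMES[2]
    return [
        _profile(
            "Neutrophil",
            {"Ly6G": "hi", "CD11b": "pos", "CD24": "pos", "CD62L": "pos"},
            {gran: 4_000.0},
            (105.0, 10.0, 150.0, 14.0),
        ),
        _profile(
            "Monocyte (inflammatory)",
            {"CD11b": "pos", "Ly6C": "pos", "CD62L": "pos"},
            {gran: 3_000.0},
            (100.0, 9.0, 55.0, 7.0),
        ),
        _profile(
            "Monocyte (resident)",
            {"CD11b": "pos", "CD11c": "pos", "CX3CR1": "pos"},
            {gran: 3_000.0},
            (100.0, 9.0, 55.0, 7.0),
        ),
        _profile(
            "Eosinophil",
            {"CD11b": "pos", "CD24": "pos", "Ly6C": "low"},
            {gran: 4_500.0},
            (120.0, 11.0, 175.0, 15.0),
        ),
        _profile(
            "cDC1",
            {"CD11c": "pos", "MHCII": "pos", "CD103": "pos", "CD24": "pos"},
            {gran: 3_500.0},
            (112.0, 10.0, 112.0, 11.0),
        ),
        _profile(
            "cDC2",
            {"CD11c": "pos", "MHCII": "pos", "CD11b": "pos", "CD24": "pos"},
            {gran: 3_500.0, mac: 2_500.0},
            (115.0, 10.0, 118.0, 11.0),
        ),
        _profile(
            "pDC",
            {"CD11c": "pos", "MHCII": "pos", "Ly6C": "pos"},
            {gran: 2_500.0},
            (88.0, 9.0, 72.0, 8.0),
        ),
        _profile(
            "Alveolar macrophage",
            {
                "CD64": "pos",
                "CD11c": "pos",
                "CD11b": "low",
                "MHCII": "low",
                "CD206": "pos",
            },
            {mac: 40_000.0},
            (170.0, 16.0, 195.0, 18.0),
        ),
        _profile(
            "Interstitial macrophage",
            {"CD64": "pos", "CD11b": "pos", "MHCII": "pos", "CX3CR1": "pos"},
            {gran: 3_000.0, mac: 1_000.0},
            (132.0, 12.0, 140.0, 13.0),
        ),
        _profile(
            "B cell",
            {"CD19": "pos", "MHCII": "pos"},
            {lym: 2_500.0},
            (76.0, 8.0, 42.0, 6.0),
        ),
        _profile(
            "T helper",
            {"CD3": "pos", "CD4": "pos", "CD127": "pos", "CD62L": "pos", "CD44": "low"},
            {lym: 2_500.0},
            (78.0, 8.0, 44.0, 6.0),
        ),
        _profile(
            "Treg",
            {
                "CD3": "pos",
                "CD4": "pos",
                "CD25": "pos",
                "CD127": "low",
                "CD44": "pos",
                "CTLA-4": "pos",
            },
            {lym: 2_500.0},
            (78.0, 8.0, 44.0, 6.0),
        ),
        _profile(
            "Cytotoxic T",
            {"CD3": "pos", "CD8": "pos", "CD127": "pos", "CD62L": "pos", "CD44": "low"},
            {lym: 2_500.0},
            (78.0, 8.0, 44.0, 6.0),
        ),
        _profile(
            "NK",
            {"CD335": "pos", "CD11b": "low", "KLRG1": "pos", "CD122": "pos"},
            {lym: 2_500.0},
            (82.0, 8.0, 48.0, 6.0),
        ),
        _profile(
            "ILC1",
            {"CD335": "pos", "CD127": "pos", "CD122": "pos"},
            {lym: 2_500.0},
            (80.0, 8.0, 46.0, 6.0),
        ),
        _profile(
            "ILC2",
            {"CD127": "pos", "CD25": "pos", "KLRG1": "pos"},
            {lym: 2_500.0},
            (80.0, 8.0, 46.0, 6.0),
        ),
        _profile(
            "ILC3",
            {"CD127": "pos"},
            {lym: 2_500.0},
            (80.0, 8.0, 46.0, 6.0),
        ),
    ]


# --------------------------------------------------------------------------
# Event simulation
# --------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Log-normal draws with exact mean ``mean`` and coefficient of variation ``cv``."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0.0:
        return mean.copy()
    sigma2 = np.log1p(cv**2)
    out = np.zeros_like(mean)
    pos = mean > 0
    mu = np.log(mean[pos]) - sigma2 / 2.0
    out[pos] = np.exp(rng.normal(mu, np.sqrt(sigma2)))
    return out


def _stack_endmembers(
    endmembers: Mapping[str, SpectralSignature] | Sequence[SpectralSignature],
) -> dict[str, SpectralSignature]:
    if isinstance(endmembers, Mapping):
        return dict(endmembers)
    return {s.name: s for s in endmembers}


def _noise(rng, clean: np.ndarray, noise: NoiseModel) -> np.ndarray:
    raw = clean.copy()
    if noise.shot_coefficient > 0:
        raw = raw + rng.normal(
            0.0, np.sqrt(noise.shot_coefficient * np.clip(clean, 0.0, None))
        )
    if noise.electronic_sd > 0:
        raw = raw + rng.normal(0.0, noise.electronic_sd, size=raw.shape)
    return np.clip(raw, 0.0, None)


def simulate_sample(
    profiles: Sequence[PopulationProfile],
    weights: Sequence[float],
    panel: PanelConfig,
    endmembers: Mapping[str, SpectralSignature] | Sequence[SpectralSignature],
    noise: NoiseModel = NoiseModel(),
    n_events: int = 20_000,
    seed: int = 0,
    carrier: str = "cells",
    perturbed: Sequence[str] = CELL_SHIFTED_DEFAULT,
    layout: DetectorLayout = AURORA_5L,
) -> EventTable:
    """Simulate a fully stained multi-population sample with ground truth.

    Each event draws a population from ``weights``, then a log-normal
    abundance per fluorochrome at its level-dependent mean; the raw signal is
    endmember matrix × abundance plus noise.  With ``carrier="cells"`` (the
    default, matching a real stained cell sample) the designated
    cell-shifted fluorochromes use their cell-bound spectral variants.
    Truth labels and abundances are stored; dead cells (1 − viability) are
    viability-dye-positive and labeled ``"Dead"``.
    """
    profiles = list(profiles)
    weights = np.asarray(weights, dtype=float)
    if len(profiles) != weights.size:
        raise ValueError("weights length must match profiles")
    if n_events < 1:
        raise ValueError("need at least one event")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixing weights must sum to 1")
    ems = _stack_endmembers(endmembers)
    af_names = [n for n in ems if n not in panel.fluorochromes]
    names = list(panel.fluorochromes) + af_names
    cols = []
    for name in names:
        sig = ems[name]
        if carrier == "cells" and name in perturbed:
            sig = cell_variant(sig)
        cols.append(sig.values)
    mat = np.column_stack(cols)  # detectors × endmembers
    if mat.shape[0] != layout.n_detectors:
        raise ValueError("endmember spectra do not match the layout")

    rng = np.random.default_rng(seed)
    pop_idx = rng.choice(len(profiles), size=n_events, p=weights)
    abund = np.zeros((n_events, len(names)))
    labels = np.empty(n_events, dtype=object)
    fsc = np.zeros(n_events)
    ssc = np.zeros(n_events)
    for p, prof in enumerate(profiles):
        mask = pop_idx == p
        m = int(mask.sum())
        if m == 0:
            continue
        labels[mask] = prof.name
        means = np.empty((m, len(names)))
        for j, name in enumerate(names):
            if name in af_names:
                means[:, j] = prof.af_weights.get(name, 0.0)
            else:
                marker = panel.marker_of(name)
                if marker == "Viability":
                    means[:, j] = LEVELS["neg"]
                else:
                    means[:, j] = LEVELS[prof.level_of(marker)]
        dead = rng.random(m) < (1.0 - prof.viability)
        viab_j = names.index(panel.viability_channel)
        means[dead, viab_j] = LEVELS["hi"]
        abund[mask] = _lognormal(rng, means, noise.abundance_cv)
        dead_idx = np.flatnonzero(mask)[dead]
        labels[dead_idx] = DEAD_LABEL
        fsc_mean, fsc_sd, ssc_mean, ssc_sd = prof.scatter
        fsc[mask] = rng.normal(fsc_mean, fsc_sd, size=m)
        ssc[mask] = rng.normal(ssc_mean, ssc_sd, size=m)
    af_total = abund[:, len(panel.fluorochromes):].sum(axis=1)
    ssc = np.clip(ssc + SSC_AF_SLOPE * af_total, 1.0, None)
    fsc = np.clip(fsc, 1.0, None)
    fsc_h = 0.95 * fsc * (1.0 + rng.normal(0.0, 0.02, size=n_events))
    clean = abund @ mat.T
    raw = _noise(rng, clean, noise)
    scatter = pd.DataFrame({"FSC-A": fsc, "SSC-A": ssc, "FSC-H": fsc_h})
    return EventTable(
        raw=raw,
        scatter=scatter,
        layout=layout,
        truth_labels=labels,
        truth_abundances=abund,
        truth_names=tuple(names),
        seed=seed,
    )


def simulate_unstained(
    profiles: Sequence[PopulationProfile],
    af_endmembers: Sequence[SpectralSignature],
    noise: NoiseModel = NoiseModel(),
    n_events: int = 6_000,
    seed: int = 0,
    weights: Sequence[float] | None = None,
    layout: DetectorLayout = AURORA_5L,
) -> EventTable:
    """Simulate an unstained lung-like sample (AF + noise only).

    All fluorochrome abundances are zero; each event carries its population's
    AF load, and SSC-A is linearly linked to total AF so that scatter-based
    AF dissection sees the AF structure.
    """
    profiles = list(profiles)
    if weights is None:
        weights = np.full(len(profiles), 1.0 / len(profiles))
    weights = np.asarray(weights, dtype=float)
    if len(profiles) != weights.size:
        raise ValueError("weights length must match profiles")
    af_endmembers = list(af_endmembers)
    names = [s.name for s in af_endmembers]
    rng = np.random.default_rng(seed)
    pop_idx = rng.choice(len(profiles), size=n_events, p=weights / weights.sum())
    abund = np.zeros((n_events, len(names)))
    labels = np.empty(n_events, dtype=object)
    fsc = np.zeros(n_events)
    ssc = np.zeros(n_events)
    for p, prof in enumerate(profiles):
        mask = pop_idx == p
        m = int(mask.sum())
        if m == 0:
            continue
        labels[mask] = prof.name
        if names:
            means = np.tile([prof.af_weights.get(n, 0.0) for n in names], (m, 1))
            abund[mask] = _lognormal(rng, means, noise.abundance_cv)
        fsc_mean, fsc_sd, ssc_mean, ssc_sd = prof.scatter
        fsc[mask] = rng.normal(fsc_mean, fsc_sd, size=m)
        ssc[mask] = rng.normal(ssc_mean, ssc_sd, size=m)
    af_total = abund.sum(axis=1)
    ssc = np.clip(ssc + SSC_AF_SLOPE * af_total, 1.0, None)
    fsc = np.clip(fsc, 1.0, None)
    fsc_h = 0.95 * fsc * (1.0 + rng.normal(0.0, 0.02, size=n_events))
    if names:
        clean = abund @ np.column_stack([s.values for s in af_endmembers]).T
    else:
        clean = np.zeros((n_events, layout.n_detectors))
    raw = _noise(rng, clean, noise)
    return EventTable(
        raw=raw,
        scatter=pd.DataFrame({"FSC-A": fsc, "SSC-A": ssc, "FSC-H": fsc_h}),
        layout=layout,
        truth_labels=labels,
        truth_abundances=abund if names else None,
        truth_names=tuple(names) if names else None,
        seed=seed,
    )


def simulate_blank(
    noise: NoiseModel = NoiseModel(),
    n_events: int = 2_000,
    seed: int = 0,
    carrier: str = "beads",
    af_endmembers: Sequence[SpectralSignature] = (),
    af_mean: float = 1_500.0,
    layout: DetectorLayout = AURORA_5L,
) -> EventTable:
    """Unstained carrier events: pure noise for beads, noise + AF for cells."""
    rng = np.random.default_rng(seed)
    clean = np.zeros((n_events, layout.n_detectors))
    if carrier == "cells" and af_endmembers:
        means = np.full((n_events, len(af_endmembers)), af_mean)
        af_ab = _lognormal(rng, means, noise.abundance_cv)
        clean = af_ab @ np.column_stack([s.values for s in af_endmembers]).T
    raw = _noise(rng, clean, noise)
    if carrier == "beads":
        fsc = np.clip(rng.normal(100.0, 4.0, n_events), 1.0, None)
        ssc = np.clip(rng.normal(30.0, 3.0, n_events), 1.0, None)
    else:
        fsc = np.clip(rng.normal(90.0, 10.0, n_events), 1.0, None)
        ssc = np.clip(rng.normal(60.0, 10.0, n_events), 1.0, None)
    fsc_h = 0.95 * fsc
    return EventTable(
        raw=raw,
        scatter=pd.DataFrame({"FSC-A": fsc, "SSC-A": ssc, "FSC-H": fsc_h}),
        layout=layout,
        seed=seed,
    )


def simulate_single_stain_controls(
    panel: PanelConfig,
    endmembers: Mapping[str, SpectralSignature] | Sequence[SpectralSignature],
    carrier: str = "beads",
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_events: int = 2_000,
    positive_fraction: float = 0.5,
    positive_mean: float = 50_000.0,
    perturbed: Sequence[str] = CELL_SHIFTED_DEFAULT,
    af_endmembers: Sequence[SpectralSignature] = (),
    af_mean: float = 1_500.0,
    layout: DetectorLayout = AURORA_5L,
) -> dict[str, EventTable]:
    """One single-stain control table per panel fluorochrome.

    Each control holds a bright positive and a negative population.  Bead
    carriers use the unperturbed spectra and carry no AF; cell carriers use
    the cell-bound spectral variants for the designated fluorochromes and add
    an AF background shared with :func:`simulate_blank`.
    """
    if carrier not in {"beads", "cells"}:
        raise ValueError("carrier must be 'beads' or 'cells'")
    ems = _stack_endmembers(endmembers)
    missing = [f for f in panel.fluorochromes if f not in ems]
    if missing:
        raise KeyError(f"no endmember spectrum for fluorochrome(s) {missing}")
    af_endmembers = list(af_endmembers)
    out: dict[str, EventTable] = {}
    for k, fluor in enumerate(panel.fluorochromes):
        rng = np.random.default_rng((seed, k))
        sig = ems[fluor]
        if carrier == "cells" and fluor in perturbed:
            sig = cell_variant(sig)
        n_pos = int(round(positive_fraction * n_events))
        abund = np.zeros(n_events)
        abund[:n_pos] = _lognormal(
            rng, np.full(n_pos, positive_mean), noise.abundance_cv
        )
        clean = np.outer(abund, sig.values)
        truth_names = [fluor]
        truth_ab = abund[:, None]
        if carrier == "cells" and af_endmembers:
            means = np.full((n_events, len(af_endmembers)), af_mean)
            af_ab = _lognormal(rng, means, noise.abundance_cv)
            clean = clean + af_ab @ np.column_stack(
                [s.values for s in af_endmembers]
            ).T
            truth_names += [s.name for s in af_endmembers]
            truth_ab = np.hstack([truth_ab, af_ab])
        raw = _noise(rng, clean, noise)
        labels = np.where(np.arange(n_events) < n_pos, "positive", "negative").astype(
            object
        )
        if carrier == "beads":
            fsc = np.clip(rng.normal(100.0, 4.0, n_events), 1.0, None)
            ssc = np.clip(rng.normal(30.0, 3.0, n_events), 1.0, None)
        else:
            fsc = np.clip(rng.normal(90.0, 10.0, n_events), 1.0, None)
            ssc = np.clip(rng.normal(60.0, 10.0, n_events), 1.0, None)
        out[fluor] = EventTable(
            raw=raw,
            scatter=pd.DataFrame({"FSC-A": fsc, "SSC-A": ssc, "FSC-H": 0.95 * fsc}),
            layout=layout,
            truth_labels=labels,
            truth_abundances=truth_ab,
            truth_names=tuple(truth_names),
            seed=seed,
        )
    return out
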
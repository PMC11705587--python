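"""End-to-end orchestration: simulate → controls → AF dissection → unmix →
gate → QC, with content-hashed manifests for reproducibility.

Every stage writes plain-text artifacts (CSV/JSON) into the run directory
and records their SHA-256 in the manifest; re-running with the same
configuration and seeds reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import af as af_mod
from . import io as io_mod
from .controls import carrier_qc, choose_carrier
from .gating import GateTreeClassifier, evaluate_recovery, marker_frame
from .simulate import (
    NoiseModel,
    default_endmembers,
    default_lung_profiles,
    default_panel,
    simulate_sample,
    simulate_single_stain_controls,
    simulate_unstained,
)
from .unmix import build_mixing_matrix, unmix_ols

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic-demo pipeline run."""

    out_dir: str = "lungspectra_run"
    seed: int = 1
    n_events: int = 20_000
    n_unstained: int = 6_000
    n_control_events: int = 1_000
    shot_coefficient: float = 0.5
    electronic_sd: float = 1.0
    abundance_cv: float = 0.35
    grid: tuple[int, int] = (7, 5)
    prune_threshold: float = 0.98
    max_af: int = 12
    select_tol: float = 0.05
    unmix_method: str = "ols"
    gate_tree: str | None = None  # optional path to a YAML tree override

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.gate_tree is not None and not Path(self.gate_tree).exists():
            raise FileNotFoundError(f"gate tree file not found: {self.gate_tree}")
        if self.unmix_method not in {"ols", "wls", "nnls"}:
            raise ValueError(f"unknown unmix method {self.unmix_method!r}")

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.shot_coefficient, self.electronic_sd, self.abundance_cv)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on synthetic data and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {name: _sha256(p) for name, p in outputs.items()},
            }
        )

    noise = config.noise
    seed = config.seed
    panel = default_panel()
    profiles = default_lung_profiles()
    endmembers = default_endmembers(seed=seed)
    af_truth = [endmembers[n] for n in endmembers if n not in panel.fluorochromes]
    fluor_sigs = [endmembers[f] for f in panel.fluorochromes]

    # stage 1: simulate
    weights = np.full(len(profiles), 1.0 / len(profiles))
    sample = simulate_sample(
        profiles, weights, panel, endmembers, noise, config.n_events, seed
    )
    unstained = simulate_unstained(
        profiles, af_truth, noise, config.n_unstained, seed + 1
    )
    p1 = out / "endmembers.csv"
    io_mod.signatures_to_csv(list(endmembers.values()), p1)
    p2 = out / "sample.csv"
    io_mod.event_table_to_csv(sample, p2)
    record("simulate", {"endmembers": p1, "sample": p2})

    # stage 2: controls + carrier choice
    bead_controls = simulate_single_stain_controls(
        panel, endmembers, "beads", noise, seed + 2, config.n_control_events
    )
    cell_controls = simulate_single_stain_controls(
        panel, endmembers, "cells", noise, seed + 3, config.n_control_events,
        af_endmembers=af_truth,
    )
    bead_qc, cell_qc, bead_sigs, cell_sigs = carrier_qc(
        bead_controls, cell_controls, panel, noise, seed + 4, af_endmembers=af_truth
    )
    choice = choose_carrier(bead_qc, cell_qc)
    p3 = out / "carrier_choice.json"
    p3.write_text(json.dumps(choice, indent=1, sort_keys=True))
    p4 = out / "stain_indices.csv"
    pd.DataFrame(
        {"beads": bead_qc.stain_indices, "cells": cell_qc.stain_indices}
    ).to_csv(p4, float_format="%.6g")
    record("controls", {"carrier_choice": p3, "stain_indices": p4})

    # stage 3: AF dissection and selection
    selector = af_mod.AutofluorescenceSelector(
        grid=config.grid,
        prune_threshold=config.prune_threshold,
        max_af=config.max_af,
        tol=config.select_tol,
    ).fit(unstained, fluor_sigs)
    p5 = out / "af_selection.json"
    p5.write_text(
        json.dumps(
            {
                "members": selector.selected_.members,
                "trace": selector.selected_.selection_trace,
            },
            indent=1,
            default=float,
        )
    )
    p6 = out / "af_signatures.csv"
    io_mod.signatures_to_csv(selector.selected_.signatures, p6)
    record("af_dissection", {"selection": p5, "signatures": p6})

    # stage 4: unmix with the carrier-chosen endmembers + selected AF
    chosen_sigs = [
        cell_sigs[f] if choice[f] == "cells" else bead_sigs[f]
        for f in panel.fluorochromes
    ]
    matrix = build_mixing_matrix(chosen_sigs, selector.selected_)
    unmixed = unmix_ols(sample, matrix)
    p7 = out / "unmixed.csv"
    unmixed.to_frame().to_csv(p7, index=False, float_format="%.6g")
    record("unmix", {"abundances": p7})

    # stage 5: gate
    X = marker_frame(unmixed, sample.scatter, panel)
    clf = GateTreeClassifier().fit(X, sample.truth_labels)
    gated = clf.gate(X)
    p8 = out / "frequency_table.csv"
    gated.frequency_table.to_csv(p8, index=False, float_format="%.6g")
    p9 = out / "labels.csv"
    pd.DataFrame(
        {"event": np.arange(len(X)), "label": gated.labels, "substate": gated.substates}
    ).to_csv(p9, index=False)
    record("gate", {"frequency_table": p8, "labels": p9})

    # stage 6: QC / recovery report
    report = evaluate_recovery(sample.truth_labels, gated.labels)
    p10 = out / "recovery.json"
    p10.write_text(
        json.dumps(
            {
                "accuracy": report.accuracy,
                "recall": {k: float(v) for k, v in report.recall.items()},
                "precision": {k: float(v) for k, v in report.precision.items()},
            },
            indent=1,
            sort_keys=True,
        )
    )
    record("qc", {"recovery": p10})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
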
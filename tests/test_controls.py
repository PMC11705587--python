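"""Control extraction, stain index, spillover spreading, carrier choice."""

import numpy as np
import pytest

import lungspectra as ls
from lungspectra.controls import (
    carrier_qc,
    choose_carrier,
    extract_signature,
    robust_sd,
    spread_matrix,
    stain_index,
    QCReport,
)
from lungspectra.simulate import (
    CELL_SHIFTED_DEFAULT,
    simulate_blank,
    simulate_single_stain_controls,
)
from lungspectra.spectral import normalize_signature, similarity_index
from lungspectra.unmix import build_mixing_matrix, unmix_ols


@pytest.fixture(scope="module")
def bead_controls(panel, endmembers):
    return simulate_single_stain_controls(
        panel, endmembers, "beads", ls.NoiseModel(), seed=21, n_events=800
    )


@pytest.fixture(scope="module")
def bead_blank():
    return simulate_blank(ls.NoiseModel(), 800, seed=21, carrier="beads")


class TestExtractSignature:
    def test_recovers_planted_endmembers_at_default_noise(
        self, bead_controls, bead_blank, endmembers, panel
    ):
        for f in panel.fluorochromes[::5]:
            sig = extract_signature(bead_controls[f], bead_blank, 0.25, name=f)
            assert similarity_index(sig, endmembers[f]) >= 0.999

    def test_recovery_across_seeds(self, panel, endmembers):
        # a thinned version of the 100-seed recovery contract
        for seed in range(10):
            controls = simulate_single_stain_controls(
                panel, endmembers, "beads", ls.NoiseModel(), seed=seed, n_events=400
            )
            blank = simulate_blank(ls.NoiseModel(), 400, seed=seed, carrier="beads")
            sig = extract_signature(controls["FITC"], blank, 0.25)
            assert similarity_index(sig, endmembers["FITC"]) >= 0.999

    def test_control_identical_to_unstained_gives_zero_signature(self, bead_blank):
        sig = extract_signature(bead_blank, bead_blank, 0.25)
        assert np.all(sig.values == 0.0)
        assert sig.peak_intensity == 0.0

    def test_stable_under_positive_fraction_choice(self, bead_controls, bead_blank):
        a = extract_signature(bead_controls["PE"], bead_blank, 0.5)
        b = extract_signature(bead_controls["PE"], bead_blank, 0.2)
        assert similarity_index(a, b) >= 0.99

    def test_too_few_events_is_an_error(self, bead_controls, bead_blank):
        from lungspectra.simulate import EventTable
        import pandas as pd

        small = EventTable(
            raw=bead_controls["PE"].raw[:50],
            scatter=bead_controls["PE"].scatter.iloc[:50].reset_index(drop=True),
        )
        with pytest.raises(ValueError, match="events"):
            extract_signature(small, bead_blank)


class TestStainIndex:
    def test_direct_formula_evaluation(self):
        # negative crafted so that robust SD = 1.4826 * MAD = 50 exactly
        x = 50.0 / 1.4826
        negative = np.array([100 - x, 100.0, 100 + x] * 10)
        positive = np.full(30, 1000.0)
        assert stain_index(positive, negative) == pytest.approx(9.0)

    def test_identical_distributions_give_near_zero(self):
        rng = np.random.default_rng(0)
        values = rng.normal(100, 10, 2000)
        assert abs(stain_index(values, values)) < 1e-12

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        neg = rng.normal(50, 5, 500)
        pos = rng.normal(500, 20, 500)
        assert stain_index(pos, neg) == pytest.approx(stain_index(pos + 37, neg + 37))

    def test_scales_inversely_with_negative_spread(self):
        x = 10.0 / 1.4826
        neg = np.array([0 - x, 0.0, 0 + x] * 10)
        pos = np.full(30, 100.0)
        assert stain_index(pos, neg) == pytest.approx(stain_index(pos, 3 * neg) * 3)

    def test_zero_negative_spread_warns_and_returns_inf(self):
        with pytest.warns(UserWarning, match="zero robust SD"):
            assert stain_index(np.full(20, 10.0), np.full(20, 1.0)) == np.inf

    def test_robust_sd_matches_mad_definition(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert robust_sd(values) == pytest.approx(1.4826 * 1.0)


def _toy_panel_controls(noise, seed, sims=(0.9, 0.2)):
    """5-endmember toy panel; the first two endmembers are near-identical."""
    rng = np.random.default_rng(seed)
    base = np.zeros((5, 16))
    for i in range(5):
        base[i, 3 * i : 3 * i + 3] = (1.0, 2.0, 1.0)
    base[1] = 0.92 * base[0] + 0.4 * base[1]  # similarity > 0.8 with endmember 0
    sigs = [normalize_signature(v, mode="unit", name=f"E{i}") for i, v in enumerate(base)]
    from lungspectra.spectral import DetectorLayout

    layout = DetectorLayout(lasers=(("CH", 16),))
    matrix = build_mixing_matrix(sigs, layout=layout)
    results = {}
    for i, sig in enumerate(sigs):
        abund = np.zeros((600, 5))
        abund[:300, i] = rng.lognormal(np.log(10_000), 0.3, 300)
        clean = abund @ matrix.matrix.T
        if noise > 0:
            raw = clean + rng.normal(0, np.sqrt(noise * np.clip(clean, 0, None) + 1e-12))
        else:
            raw = clean
        results[sig.name] = unmix_ols(raw, matrix)
    return sigs, results


class TestSpreadMatrix:
    def test_zero_noise_controls_give_zero_spread(self):
        _, results = _toy_panel_controls(noise=0.0, seed=2)
        mat = spread_matrix(results)
        np.testing.assert_allclose(mat.to_numpy(), 0.0, atol=1e-9)

    def test_diagonal_is_identically_zero(self):
        _, results = _toy_panel_controls(noise=0.5, seed=3)
        assert np.all(np.diag(spread_matrix(results).to_numpy()) == 0.0)

    def test_shot_noise_increases_total_spread(self):
        _, low = _toy_panel_controls(noise=0.5, seed=4)
        _, high = _toy_panel_controls(noise=5.0, seed=4)
        assert spread_matrix(high).to_numpy().sum() > spread_matrix(low).to_numpy().sum()

    def test_most_similar_pair_spreads_most(self):
        sigs, results = _toy_panel_controls(noise=2.0, seed=5)
        assert similarity_index(sigs[0], sigs[1]) > 0.8
        mat = spread_matrix(results).to_numpy()
        off = mat[~np.eye(5, dtype=bool)]
        assert max(mat[0, 1], mat[1, 0]) == pytest.approx(off.max())


class TestChooseCarrier:
    def _qc(self, carrier, spread, si):
        import pandas as pd

        fluors = list(spread) + ["_sink"]
        frame = pd.DataFrame(0.0, index=fluors, columns=fluors)
        for f, total in spread.items():
            frame.loc[f, "_sink"] = total
        return QCReport(carrier, dict(si), frame)

    def test_lower_spread_wins(self):
        bead = self._qc("beads", {"A": 0.1, "B": 0.2}, {"A": 5, "B": 5})
        cell = self._qc("cells", {"A": 0.5, "B": 0.6}, {"A": 50, "B": 50})
        assert choose_carrier(bead, cell) == {"A": "beads", "B": "beads"}

    def test_spread_tie_broken_by_stain_index(self):
        bead = self._qc("beads", {"A": 0.5}, {"A": 5})
        cell = self._qc("cells", {"A": 0.5}, {"A": 50})
        assert choose_carrier(bead, cell) == {"A": "cells"}

    def test_coverage_mismatch_is_an_error(self):
        bead = self._qc("beads", {"A": 0.1}, {"A": 5})
        cell = self._qc("cells", {"B": 0.1}, {"B": 5})
        with pytest.raises(ValueError, match="different fluorochromes"):
            choose_carrier(bead, cell)

    def test_cell_shifted_channels_choose_cells(self, panel, endmembers, af_truth):
        noise = ls.NoiseModel()
        beads = simulate_single_stain_controls(
            panel, endmembers, "beads", noise, seed=31, n_events=600
        )
        cells = simulate_single_stain_controls(
            panel, endmembers, "cells", noise, seed=32, n_events=600,
            af_endmembers=af_truth,
        )
        bead_qc, cell_qc, _, _ = carrier_qc(
            beads, cells, panel, noise, seed=33, af_endmembers=af_truth
        )
        choice = choose_carrier(bead_qc, cell_qc)
        for f in CELL_SHIFTED_DEFAULT:
            assert choice[f] == "cells"
        # beads remain the carrier for most antibodies
        unperturbed = [f for f in panel.fluorochromes if f not in CELL_SHIFTED_DEFAULT]
        beads_chosen = sum(choice[f] == "beads" for f in unperturbed)
        assert beads_chosen > 0.5 * len(unperturbed)
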
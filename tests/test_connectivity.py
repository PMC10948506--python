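import numpy as np
import pandas as pd
import pytest

from numadapt.connectivity import (
    compare_ispc,
    ispc,
    ispc_matrix,
    narrowband_phase,
    pair_labels,
    surface_laplacian,
)
from numadapt.evoked import selective_average
from numadapt.io import EpochArray
from numadapt.simulate import EEGEffectSpec, simulate_eeg
from numadapt import splines

from conftest import make_epochs


def full_design(n_per_cell=2, conditions=("High", "Low")):
    rows = []
    trial = 0
    for cond in conditions:
        for num in (14, 16, 18, 20, 22):
            for _ in range(n_per_cell):
                rows.append((0, 0, trial, cond, num))
                trial += 1
    return pd.DataFrame(
        rows, columns=["participant", "block", "trial", "adaptation", "numerosity"]
    )


class TestSurfaceLaplacian:
    def test_constant_field_maps_to_zero(self, montage, rng):
        c = rng.normal(size=2500)
        epochs = make_epochs(np.tile(c, (2, 30, 1)), montage)
        out = surface_laplacian(epochs)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_linearity(self, montage, rng):
        epochs = make_epochs(rng.normal(size=(1, 30, 100)), montage)
        out1 = surface_laplacian(epochs)
        out7 = surface_laplacian(epochs.copy_with(7.0 * epochs.data))
        np.testing.assert_allclose(out7.data, 7.0 * out1.data, atol=1e-9)

    def test_decorrelates_volume_conducted_field(self, montage, rng):
        # low-rank smooth field + small sensor noise: the Laplacian must
        # reduce the mean absolute inter-channel correlation
        patterns = np.exp(
            -np.arccos(np.clip(montage.positions @ montage.positions[:3].T, -1, 1)) ** 2
        )
        sources = rng.normal(size=(3, 500))
        data = (patterns @ sources + 0.05 * rng.normal(size=(30, 500)))[None]
        epochs = make_epochs(data, montage)
        out = surface_laplacian(epochs)

        def mean_abs_corr(x):
            c = np.corrcoef(x)
            return np.abs(c[~np.eye(30, dtype=bool)]).mean()

        assert mean_abs_corr(out.data[0]) < mean_abs_corr(epochs.data[0])

    def test_duplicate_positions_rejected(self, montage):
        pos = montage.positions.copy()
        pos[1] = pos[0]
        from numadapt.montage import Montage

        bad = Montage(montage.labels, pos)
        with pytest.raises(ValueError, match="duplicate"):
            splines.laplacian_operator(bad)


class TestNarrowbandPhase:
    def _evoked(self, montage, trace):
        return selective_average(
            make_epochs(np.tile(trace, (1, 30, 1)), montage), "High"
        )

    @pytest.mark.parametrize("f", [4.0, 5.0])  # integer cycles per epoch
    def test_pure_tone_instantaneous_frequency_and_envelope(self, montage, f):
        t = np.arange(2500) * 2.0 - 500.0
        ev = self._evoked(montage, np.sin(2 * np.pi * f * t / 1000.0))
        an = narrowband_phase(ev, f)
        phase = np.unwrap(an.phase[0])
        inst_f = np.diff(phase)[an.valid[1:]] * 500.0 / (2 * np.pi)
        assert np.all(np.abs(inst_f - f) < 0.05)
        env = an.envelope[0, an.valid]
        assert env.std() / env.mean() < 0.01

    @pytest.mark.parametrize("num", [14, 16, 18, 20, 22])
    def test_windowed_tagging_tone_phase_fidelity(self, montage, num):
        # the physically realistic signal: tone active only during the test
        # window; onset/offset transients of the narrow filter ring into the
        # valid region, bounding the achievable fidelity
        f = num / 4.0
        t = np.arange(2500) * 2.0 - 500.0
        active = (t >= 0) & (t < 4000)
        ev = self._evoked(montage, np.sin(2 * np.pi * f * t / 1000.0) * active)
        an = narrowband_phase(ev, f)
        phase = np.unwrap(an.phase[0])
        inst_f = np.diff(phase)[an.valid[1:]] * 500.0 / (2 * np.pi)
        assert np.all(np.abs(inst_f - f) < 0.1)
        env = an.envelope[0, an.valid]
        assert env.std() / env.mean() < 0.05

    def test_out_of_band_tone_attenuated(self, montage):
        t = np.arange(2500) * 2.0 - 500.0
        ev4 = self._evoked(montage, np.sin(2 * np.pi * 4.0 * t / 1000.0))
        ev10 = self._evoked(montage, np.sin(2 * np.pi * 10.0 * t / 1000.0))
        e4 = np.median(narrowband_phase(ev4, 4.0).envelope[0, 500:1750])
        e10 = np.median(narrowband_phase(ev10, 4.0).envelope[0, 500:1750])
        assert 20 * np.log10(e4 / e10) >= 20.0

    def test_phases_wrapped(self, montage, rng):
        ev = self._evoked(montage, rng.normal(size=2500))
        an = narrowband_phase(ev, 5.5)
        assert an.phase.min() > -np.pi - 1e-12
        assert an.phase.max() <= np.pi + 1e-12

    def test_valid_mask_trims_edges(self, montage, rng):
        an = narrowband_phase(self._evoked(montage, rng.normal(size=2500)), 4.0)
        times = -500.0 + np.arange(2500) * 2.0
        assert not an.valid[times < 500.0].any()
        assert not an.valid[times >= 3500.0].any()
        assert an.valid.sum() == 1500

    def test_band_outside_nyquist_rejected(self, montage, rng):
        ev = self._evoked(montage, rng.normal(size=2500))
        with pytest.raises(ValueError):
            narrowband_phase(ev, 0.4)  # lower edge <= 0


class TestIspcScalar:
    def test_identical_phases_give_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=2000)
        assert ispc(phi, phi, np.ones(2000, bool)) == pytest.approx(1.0)

    def test_constant_offset_invariance(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=2000)
        assert ispc(phi, phi + 0.7, np.ones(2000, bool)) == pytest.approx(1.0)
        assert ispc(phi, phi + 0.7, np.ones(2000, bool)) == pytest.approx(
            ispc(phi + 0.7, phi, np.ones(2000, bool))
        )

    def test_independent_uniform_phases_match_rayleigh_mean(self):
        # E[resultant length] of T iid uniform phasors ~ 0.886 / sqrt(T)
        rng = np.random.default_rng(0)
        t = 2000
        vals = [
            ispc(
                rng.uniform(-np.pi, np.pi, t),
                rng.uniform(-np.pi, np.pi, t),
                np.ones(t, bool),
            )
            for _ in range(1000)
        ]
        expected = 0.886 / np.sqrt(t)
        assert np.mean(vals) == pytest.approx(expected, abs=0.0015)

    def test_too_few_valid_samples_rejected(self, rng):
        phi = rng.uniform(size=200)
        mask = np.zeros(200, bool)
        with pytest.raises(ValueError, match="empty"):
            ispc(phi, phi, mask)
        mask[:50] = True
        with pytest.raises(ValueError, match="100"):
            ispc(phi, phi, mask)


@pytest.fixture(scope="module")
def sim_epochs(montage):
    rng = np.random.default_rng(7)
    return simulate_eeg(full_design(n_per_cell=3), montage, EEGEffectSpec(), rng)


class TestIspcMatrix:

    def test_matrix_contract(self, sim_epochs, montage):
        m = ispc_matrix(sim_epochs, "High")
        assert m.shape == (30, 30)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_injected_pairs_exceed_low_condition(self, sim_epochs, montage):
        mh = ispc_matrix(sim_epochs, "High")
        ml = ispc_matrix(sim_epochs, "Low")
        for a, b in EEGEffectSpec().coupling_pairs:
            i, j = montage.index(a), montage.index(b)
            assert mh[i, j] > ml[i, j]

    def test_numerosity_average_is_arithmetic_mean(self, sim_epochs):
        full = ispc_matrix(sim_epochs, "High")
        singles = [
            ispc_matrix(sim_epochs, "High", numerosities=(n,))
            for n in (14, 16, 18, 20, 22)
        ]
        np.testing.assert_allclose(full, np.mean(singles, axis=0), atol=1e-12)

    def test_amplitude_rescaling_invariance(self, sim_epochs):
        scaled = sim_epochs.copy_with(sim_epochs.data * 37.5)
        np.testing.assert_allclose(
            ispc_matrix(scaled, "Low"), ispc_matrix(sim_epochs, "Low"), atol=1e-9
        )

    def test_missing_numerosity_rejected(self, montage, rng):
        design = full_design(n_per_cell=1)
        design = design[design["numerosity"] != 18].reset_index(drop=True)
        epochs = simulate_eeg(design, montage, EEGEffectSpec(), rng)
        with pytest.raises(ValueError, match="18"):
            ispc_matrix(epochs, "High")


class TestCompareIspc:
    def test_identical_matrices_give_no_pairs(self, rng):
        m = rng.uniform(0.2, 0.8, size=(5, 10, 10))
        m = (m + m.transpose(0, 2, 1)) / 2
        labels = tuple(f"ch{i}" for i in range(10))
        res = compare_ispc(m, m.copy(), labels, n_permutations=500)
        assert res["sig_pairs"] == []
        np.testing.assert_allclose(res["p_raw"], 1.0)

    def test_pair_count_and_labels(self):
        labels = tuple("abcd")
        assert len(pair_labels(labels)) == 6
        assert pair_labels(labels)[0] == ("a", "b")

    def test_unpaired_input_rejected(self, rng):
        m = rng.uniform(size=(4, 6, 6))
        with pytest.raises(ValueError):
            compare_ispc(m, m[:3], tuple("abcdef"))
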
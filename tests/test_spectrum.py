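import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import polynematic as pn
from polynematic.spectrum import (
    block_errors,
    lattice_wavevectors,
    mode_correlation,
    qframe_axes,
    segment_weights,
)

unit_vec = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).filter(lambda v: 0.1 < np.linalg.norm(v) < 1.8)


def _single_config(rng, n0=64, box=12.0, n_chains=1):
    pos = rng.random((n0, 3)) * box
    t = rng.normal(size=(n0, 3))
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    cid = np.repeat(np.arange(n_chains), n0 // n_chains)
    return pn.ChainConfiguration(box=box, positions=pos, directions=t, chain_id=cid)


class TestChainConfiguration:
    def test_non_unit_directions_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            pn.ChainConfiguration(
                box=10.0,
                positions=np.zeros((2, 3)),
                directions=np.array([[1.0, 0, 0], [0.5, 0, 0]]),
                chain_id=np.zeros(2, int),
            )

    def test_non_contiguous_chains_rejected(self):
        t = np.tile([0.0, 0.0, 1.0], (3, 1))
        with pytest.raises(ValueError, match="contiguous"):
            pn.ChainConfiguration(
                box=10.0, positions=np.zeros((3, 3)), directions=t,
                chain_id=np.array([0, 1, 0]),
            )

    def test_density(self):
        rng = np.random.default_rng(0)
        cfg = _single_config(rng, n0=64, box=4.0)
        assert cfg.density == pytest.approx(1.0)
        assert cfg.n_chains == 1


class TestQFrame:
    def test_lab_frame_recovered(self):
        fr = qframe_axes([0, 0, 2.5], reference_axis=[1, 0, 0])
        assert np.allclose(fr.ex, [1, 0, 0])
        assert np.allclose(fr.ey, [0, 1, 0])
        assert np.allclose(fr.ez, [0, 0, 1])

    def test_degenerate_reference_falls_back(self):
        fr = qframe_axes([3.0, 0, 0], reference_axis=[1, 0, 0])
        assert np.allclose(fr.ex, [0, 1, 0])
        assert np.allclose(fr.ey, np.cross(fr.ez, fr.ex))

    def test_zero_wavevector_rejected(self):
        with pytest.raises(ValueError):
            qframe_axes([0.0, 0.0, 0.0])

    @given(q=unit_vec)
    def test_orthonormal_right_handed(self, q):
        fr = qframe_axes(q)
        m = np.stack([fr.ex, fr.ey, fr.ez])
        assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
        assert np.allclose(np.cross(fr.ex, fr.ey), fr.ez, atol=1e-12)


class TestSegmentWeights:
    def test_aligned_segment(self):
        fr = qframe_axes([0, 0, 1.0])
        w = segment_weights(np.array([0.0, 0.0, 1.0]), fr)
        assert (w["rho"], w["zz"]) == (1.0, pytest.approx(1.0))
        assert (w["xz"], w["yz"], w["xy"]) == (0.0, 0.0, 0.0)

    def test_diagonal_segment(self):
        fr = qframe_axes([0, 0, 1.0])
        t = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)
        w = segment_weights(t, fr)
        assert w["zz"] == pytest.approx(0.25)
        assert w["xz"] == pytest.approx(0.75)
        assert w["xy"] == pytest.approx(0.0, abs=1e-15)
        assert w["yz"] == pytest.approx(0.0, abs=1e-15)

    def test_isotropic_moments(self):
        """<a_zz> = 0, <a_zz^2> = 1/5, <a_xz^2> = 3/20 for uniform orientations."""
        rng = np.random.default_rng(3)
        cos = 2 * rng.random(10**6) - 1
        sin = np.sqrt(1 - cos**2)
        phi = 2 * np.pi * rng.random(10**6)
        t = np.stack([sin * np.cos(phi), sin * np.sin(phi), cos], axis=1)
        w = segment_weights(t, qframe_axes([0, 0, 1.0]))
        assert np.mean(w["zz"]) == pytest.approx(0.0, abs=5e-3)
        assert np.mean(w["zz"] ** 2) == pytest.approx(0.2, rel=5e-3)
        assert np.mean(w["xz"] ** 2) == pytest.approx(0.15, rel=5e-3)

    @given(t=unit_vec, q=unit_vec)
    def test_apolar_weights(self, t, q):
        t = np.asarray(t) / np.linalg.norm(t)
        fr = qframe_axes(q)
        w1 = segment_weights(t, fr)
        w2 = segment_weights(-t, fr)
        for name in w1:
            assert w1[name] == pytest.approx(w2[name], abs=1e-14)


class TestModeCorrelation:
    def test_single_segment_density(self):
        cfg = pn.ChainConfiguration(
            box=10.0, positions=np.array([[3.7, 1.2, 9.9]]),
            directions=np.array([[0.0, 0.0, 1.0]]), chain_id=np.zeros(1, int),
        )
        qv = np.array([2 * np.pi / 10.0, 0, 0])
        assert mode_correlation(cfg, qv, np.ones(1), np.ones(1)) == pytest.approx(1.0)

    def test_two_coincident_segments_coherent(self):
        pos = np.tile([1.0, 2.0, 3.0], (2, 1))
        cfg = pn.ChainConfiguration(
            box=10.0, positions=pos, directions=np.tile([0, 0, 1.0], (2, 1)),
            chain_id=np.zeros(2, int),
        )
        qv = np.array([0, 2 * np.pi / 10.0, 0])
        assert mode_correlation(cfg, qv, np.ones(2), np.ones(2)) == pytest.approx(2.0)

    def test_incommensurate_wavevector_rejected(self):
        rng = np.random.default_rng(0)
        cfg = _single_config(rng)
        with pytest.raises(ValueError, match="commensurate"):
            mode_correlation(cfg, [0.1, 0, 0], np.ones(64), np.ones(64))

    def test_aligned_coherent_zz_scaling(self):
        """All segments at one point, aligned perpendicular to q: value = N0 * a_zz^2."""
        n0 = 32
        cfg = pn.ChainConfiguration(
            box=10.0, positions=np.tile([5.0, 5.0, 5.0], (n0, 1)),
            directions=np.tile([1.0, 0.0, 0.0], (n0, 1)), chain_id=np.zeros(n0, int),
        )
        qv = np.array([0, 0, 2 * np.pi / 10.0])
        fr = qframe_axes(qv)
        w = segment_weights(cfg.directions, fr)
        # t perpendicular to ez: a_zz = -1/2 for every segment
        assert mode_correlation(cfg, qv, w["zz"], w["zz"]) == pytest.approx(n0 * 0.25)


class TestEstimateSpectrum:
    def test_ideal_gas_flat_spectra(self, ideal_gas_spectrum):
        """Free segments: rho = 1 (Poisson), xy = 3/20, zz = 1/5 in every shell."""
        sp = ideal_gas_spectrum
        for name, truth in (("rho", 1.0), ("xy", 0.15), ("zz", 0.2), ("cross", 0.0)):
            dev = np.abs(sp.est[name] - truth)
            # few blocks -> stderr itself is noisy; accept 4 sigma or 5% of scale
            ok = (dev < 4.0 * sp.err[name]) | (dev < 0.01)
            assert np.all(ok), (name, sp.est[name], dev / sp.err[name])
        # away from the sparsest shells the estimates are tight in absolute terms
        assert np.allclose(sp.est["rho"][2:], 1.0, atol=0.05)
        assert np.allclose(sp.est["xy"][2:], 0.15, atol=0.01)

    def test_isotropy_xz_equals_yz(self, ideal_gas_spectrum):
        sp = ideal_gas_spectrum
        joint = np.sqrt(sp.err["xz"] ** 2 + sp.err["yz"] ** 2)
        assert np.all(np.abs(sp.est["xz"] - sp.est["yz"]) < 3.0 * joint)

    def test_shells_and_metadata(self, ideal_gas_spectrum):
        sp = ideal_gas_spectrum
        assert np.all(np.diff(sp.q) > 0)
        assert sp.q[0] > 0
        assert sp.meta["N0"] == 2048
        assert sp.n_qvec[0] == 3  # (1,0,0), (0,1,0), (0,0,1) up to inversion

    def test_apolarity_bit_identical(self):
        rng = np.random.default_rng(5)
        cfg = _single_config(rng)
        flipped = pn.ChainConfiguration(
            box=cfg.box, positions=cfg.positions, directions=-cfg.directions,
            chain_id=cfg.chain_id,
        )
        s1 = pn.estimate_spectrum([cfg], n_shells=3, block_size=1)
        s2 = pn.estimate_spectrum([flipped], n_shells=3, block_size=1)
        for name in pn.spectrum.OBSERVABLES:
            assert np.array_equal(s1.est[name], s2.est[name])

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        cfg = _single_config(rng)
        shifted = pn.ChainConfiguration(
            box=cfg.box, positions=(cfg.positions + [3.1, -7.7, 0.4]) % cfg.box,
            directions=cfg.directions, chain_id=cfg.chain_id,
        )
        s1 = pn.estimate_spectrum([cfg], n_shells=3, block_size=1)
        s2 = pn.estimate_spectrum([shifted], n_shells=3, block_size=1)
        for name in pn.spectrum.OBSERVABLES:
            assert np.allclose(s1.est[name], s2.est[name], rtol=1e-9, atol=1e-10)

    def test_identical_configs_zero_stderr(self):
        rng = np.random.default_rng(7)
        cfg = _single_config(rng)
        sp = pn.estimate_spectrum([cfg, cfg, cfg, cfg], n_shells=2, block_size=1)
        for name in pn.spectrum.OBSERVABLES:
            assert np.allclose(sp.err[name], 0.0)

    def test_single_block_stderr_missing(self):
        rng = np.random.default_rng(8)
        sp = pn.estimate_spectrum([_single_config(rng)], n_shells=2, block_size=100)
        assert np.all(np.isnan(sp.err["rho"]))

    def test_inconsistent_boxes_rejected(self):
        rng = np.random.default_rng(9)
        c1 = _single_config(rng, box=12.0)
        c2 = _single_config(rng, box=10.0)
        with pytest.raises(ValueError, match="same box"):
            pn.estimate_spectrum([c1, c2])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            pn.estimate_spectrum([])


class TestLatticeWavevectors:
    def test_counts_and_dedup(self):
        n, q = lattice_wavevectors(box=10.0, qmax=2 * 2 * np.pi / 10.0)
        mags = np.linalg.norm(n, axis=1)
        assert np.all(mags > 0) and np.all(mags <= 2 + 1e-9)
        # no pair n, -n present
        keys = {tuple(v) for v in n}
        assert not any(tuple(-np.array(k)) in keys for k in keys)


class TestBlockErrors:
    def test_constant_series(self):
        assert block_errors(np.ones(500), 100) == pytest.approx(0.0)

    def test_iid_normal_matches_sqrt_n(self):
        rng = np.random.default_rng(11)
        se = block_errors(rng.normal(size=10**4), 100)
        assert se == pytest.approx(0.01, rel=0.3)

    def test_floor_rule_two_blocks(self):
        rng = np.random.default_rng(12)
        se = block_errors(rng.normal(size=250), 100)
        assert np.isfinite(se)  # exactly 2 blocks used

    def test_insufficient_blocks_nan(self):
        assert np.isnan(block_errors(np.arange(150.0), 100))


class TestOrientationDecorrelation:
    def _two_chain_config(self, dirs):
        t = np.asarray(dirs, float)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        return pn.ChainConfiguration(
            box=10.0, positions=np.zeros((len(t), 3)) + 1.0, directions=t,
            chain_id=np.repeat([0, 1], len(t) // 2),
        )

    def test_self_projection_is_one(self):
        cfg = self._two_chain_config([[0, 0, 1], [0, 0, 1], [1, 0, 0], [1, 0, 0]])
        assert pn.orientation_decorrelation([cfg], cfg)[0] == pytest.approx(1.0)

    def test_one_flipped_chain_averages_zero(self):
        cfg0 = self._two_chain_config([[0, 0, 1], [0, 0, 1], [1, 0, 0], [1, 0, 0]])
        cfg1 = self._two_chain_config([[0, 0, 1], [0, 0, 1], [-1, 0, 0], [-1, 0, 0]])
        assert pn.orientation_decorrelation([cfg1], cfg0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_randomized_ensemble_decorrelates(self):
        spec = pn.WLCSpec(Ns=4, Nc=200, epsT=2.0, L0=40.0, seed=3, n_configs=3)
        configs = pn.sample_wlc_ensemble(spec)
        series = pn.orientation_decorrelation(configs[1:], configs[0])
        assert np.all(np.abs(series) < 3.0 / np.sqrt(200))
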
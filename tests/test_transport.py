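"""Photon-packet transport physics: Beer-Lambert limits, energy conservation,
determinism, symmetry, detection gating, and fluence normalization."""

import math

import numpy as np
import pytest

from fiberdrs.mc_engine import (FiberSpec, PhotonRecord, detect_photon,
                                normalize_fluence, propagate_photon, run_simulation)
from fiberdrs.optics import OpticalProperties
from fiberdrs.synthetic_data import fixture_scene


def ledger_total(ledger):
    return (ledger["deposited"] + ledger["escaped_undetected"] + ledger["detected"]
            + ledger["roulette_lost"] + ledger["event_cap_lost"])


class TestBeerLambertLimit:
    def test_scatter_free_transmission(self):
        # without scattering, survival to depth d is exp(-mu_a d)
        scene = fixture_scene("absorbing_slab")   # mu_a = 1/mm, 4 mm deep
        n = 100_000
        res = run_simulation(scene, n, seed=3)
        mu_a, depth = 1.0, scene.extent_mm[2]
        expected = math.exp(-mu_a * depth)
        # photons escape the bottom face with their residual weight
        transmitted = res.ledger["escaped_undetected"] / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(transmitted - expected) < 3 * se + 1e-4

    def test_straight_path_without_scattering(self):
        scene = fixture_scene("absorbing_slab")
        rec = propagate_photon(scene, seed=9)
        path = rec.path
        # all interaction points lie on one straight line through the launch point
        d = path[-1] - path[0]
        d = d / np.linalg.norm(d)
        rel = path[1:] - path[0]
        cross = np.linalg.norm(np.cross(rel, d), axis=1)
        assert np.all(cross < 1e-9)

    def test_depth_resolved_fluence_profile(self):
        # normalized fluence in a pure absorber decays as exp(-mu_a z)
        scene = fixture_scene("absorbing_slab")
        res = run_simulation(scene, 200_000, seed=4)
        phi = normalize_fluence(res)
        profile = phi.sum(axis=(0, 1))
        vs = scene.voxel_size
        z = (np.arange(len(profile)) + 0.5) * vs
        keep = z < 3.0  # good statistics region
        ratio = profile[keep] / np.exp(-1.0 * z[keep])
        assert np.std(ratio) / np.mean(ratio) < 0.05


class TestConservation:
    def test_zero_absorption_deposits_nothing(self):
        scene = fixture_scene("no_absorption")
        res = run_simulation(scene, 20_000, seed=5)
        assert res.ledger["deposited"] == 0.0
        assert res.fluence.sum() == 0.0
        # everything launched escapes or is detected
        led = res.ledger
        out = led["escaped_undetected"] + led["detected"] + led["roulette_lost"]
        assert out == pytest.approx(led["launched"], rel=1e-3)

    def test_weight_ledger_closes_in_cancellous_medium(self):
        scene = fixture_scene("tiny_cancellous")
        res = run_simulation(scene, 10_000, seed=6)
        led = res.ledger
        assert abs(ledger_total(led) - led["launched"]) / led["launched"] < 1e-3

    def test_fluence_grid_equals_deposited_ledger(self):
        scene = fixture_scene("tiny_cancellous")
        res = run_simulation(scene, 5_000, seed=7)
        assert res.fluence.sum() == pytest.approx(res.ledger["deposited"], rel=1e-9)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        scene = fixture_scene("tiny_cancellous")
        a = run_simulation(scene, 20_000, seed=12)
        b = run_simulation(scene, 20_000, seed=12)
        assert a.n_detected == b.n_detected
        assert a.ledger == b.ledger
        assert np.array_equal(a.fluence, b.fluence)
        assert np.array_equal(a.paths, b.paths)

    def test_different_seed_differs(self):
        scene = fixture_scene("tiny_cancellous")
        a = run_simulation(scene, 20_000, seed=12)
        b = run_simulation(scene, 20_000, seed=13)
        assert not np.array_equal(a.fluence, b.fluence)

    def test_path_storage_independent_of_buffer_growth(self):
        # per-photon random streams: keeping all paths (tiny buffers, forced
        # rerun) must not change the physics
        scene = fixture_scene("tiny_cancellous")
        a = run_simulation(scene, 2_000, seed=12, keep_paths="none")
        b = run_simulation(scene, 2_000, seed=12, keep_paths="all")
        assert a.ledger == b.ledger
        assert np.array_equal(a.fluence, b.fluence)


class TestSymmetry:
    def test_centered_pencil_beam_fluence_symmetric(self):
        # homogeneous medium + centered vertical beam: mirror-symmetric fluence
        scene = fixture_scene("tiny_cancellous")
        cx = scene.extent_mm[0] / 2
        em = FiberSpec(center=(cx, scene.extent_mm[1] / 2, 0.0), axis=(0, 0, 1),
                       numerical_aperture=1e-6, core_diameter=1e-6)
        scene = type(scene)(
            voxel_labels=scene.voxel_labels, material_table=scene.material_table,
            voxel_size=scene.voxel_size, emitter=em, collector=scene.collector,
        )
        res = run_simulation(scene, 100_000, seed=21)
        prof = res.fluence.sum(axis=(1, 2))  # x-profile
        mirrored = prof[::-1]
        denom = prof + mirrored
        keep = denom > denom.max() * 1e-3
        asym = np.abs(prof - mirrored)[keep] / denom[keep]
        assert np.median(asym) < 0.05


class TestDetection:
    collector = FiberSpec(center=(1.0, 1.0, 0.0), axis=(0, 0, 1),
                          core_diameter=0.2, numerical_aperture=0.22,
                          role="collector")

    def _record(self, exit_xy, direction):
        path = np.array([[1.0, 1.0, 1.0], [exit_xy[0], exit_xy[1], 0.0]])
        return PhotonRecord(path=path, weights=np.array([1.0, 0.9]),
                            exit_direction=np.asarray(direction, dtype=float),
                            weight_at_exit=0.9, detected=False)

    def test_center_antiparallel_detected(self):
        rec = self._record((1.0, 1.0), (0, 0, -1.0))
        assert detect_photon(rec, self.collector)

    def test_outside_core_rejected(self):
        rec = self._record((1.15, 1.0), (0, 0, -1.0))
        assert not detect_photon(rec, self.collector)

    def test_oblique_exit_beyond_na_rejected(self):
        # 20 degrees off-axis > arcsin(0.22) ~ 12.7 degrees
        a = math.radians(20)
        rec = self._record((1.0, 1.0), (math.sin(a), 0, -math.cos(a)))
        assert not detect_photon(rec, self.collector)

    def test_exit_just_within_na_detected(self):
        a = math.asin(0.22) - 1e-3
        rec = self._record((1.05, 1.0), (math.sin(a), 0, -math.cos(a)))
        assert detect_photon(rec, self.collector)


class TestNormalizeFluence:
    def test_zero_deposition_zero_grid(self):
        scene = fixture_scene("no_absorption")
        res = run_simulation(scene, 1_000, seed=2)
        assert np.all(normalize_fluence(res) == 0.0)

    def test_invariant_under_photon_count(self):
        scene = fixture_scene("absorbing_slab")
        r1 = run_simulation(scene, 50_000, seed=31)
        r2 = run_simulation(scene, 100_000, seed=32)
        p1 = normalize_fluence(r1).sum(axis=(0, 1))
        p2 = normalize_fluence(r2).sum(axis=(0, 1))
        keep = p1 > p1.max() * 0.05  # restrict to well-sampled depths
        assert np.allclose(p1[keep], p2[keep], rtol=0.15)

    def test_zero_mu_a_maps_to_zero(self):
        scene = fixture_scene("no_absorption")
        res = run_simulation(scene, 100, seed=1)
        out = normalize_fluence(res)
        assert out.shape == scene.shape and np.all(out == 0)


class TestRefractiveBoundary:
    def test_mismatched_index_conserves_energy_and_reduces_escape(self):
        # with n = 1.4, total internal reflection traps obliquely rising
        # photons, so less weight escapes the top face than with matched index
        matched = fixture_scene("tiny_cancellous")
        res_m = run_simulation(matched, 20_000, seed=51)
        mismatched = fixture_scene("tiny_cancellous")
        mismatched.refractive_index = 1.4
        res_n = run_simulation(mismatched, 20_000, seed=51)
        led = res_n.ledger
        total = ledger_total(led)
        assert abs(total - led["launched"]) / led["launched"] < 1e-3
        assert led["deposited"] > res_m.ledger["deposited"]


class TestValidation:
    def test_bad_photon_count(self):
        scene = fixture_scene("tiny_cancellous")
        with pytest.raises(ValueError):
            run_simulation(scene, 0, seed=1)

    def test_optical_properties_invariants(self):
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=-1.0, mu_s_reduced=1.0, g=0.5)
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=1.0, mu_s_reduced=1.0, g=1.0)
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=1.0, mu_s_reduced=-1.0, g=0.5)
        p = OpticalProperties(mu_a=1.4220, mu_s_reduced=19.5129, g=0.9)
        assert p.mu_s == pytest.approx(195.129)
        assert p.mu_a_mm == pytest.approx(0.14220)
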
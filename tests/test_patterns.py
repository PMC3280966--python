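import numpy as np
import pytest

from lungbud.config import make_fixture
from lungbud.patterns import (PatternConfig, Spot, analyze, axial_spacing,
                              branch_events, classify_mode, detect_spots)
from lungbud.solve import FieldState


def _spot(x, y, zone, value=1.0):
    return Spot(node=0, x=x, y=y, value=value, zone=zone)


class TestDetectSpots:
    def test_recovers_planted_gaussian_bumps(self):
        mesh, field, centers = make_fixture("gaussian_spots_field", seed=1)
        spots = detect_spots(mesh, field)
        assert len(spots) == len(centers)
        found = np.array([[s.x, s.y] for s in spots])
        for c in centers:
            d = np.hypot(*(found - c).T).min()
            assert d < 0.2    # within ~mesh resolution of the planted centre

    def test_single_bump_below_threshold_ignored(self):
        mesh, field, centers = make_fixture("gaussian_spots_field", seed=1)
        # one dominant bump: secondary bumps below the relative threshold
        d2 = ((mesh.points - centers[0]) ** 2).sum(axis=1)
        field = field + 20.0 * np.exp(-d2 / (2 * 0.25 ** 2))
        spots = detect_spots(mesh, field, PatternConfig(theta_rel=0.3))
        assert len(spots) == 1

    def test_all_zero_field_yields_no_spots(self):
        mesh = make_fixture("tiny_mesh")
        assert detect_spots(mesh, np.zeros(mesh.n_nodes)) == []

    def test_detection_invariant_to_uniform_rescaling(self):
        mesh, field, _ = make_fixture("gaussian_spots_field", seed=3)
        s1 = detect_spots(mesh, field)
        s2 = detect_spots(mesh, 37.5 * field)
        assert [(s.node, s.zone) for s in s1] == [(s.node, s.zone) for s in s2]

    def test_merge_radius_collapses_close_maxima(self):
        mesh, field, _ = make_fixture("gaussian_spots_field", seed=1)
        few = detect_spots(mesh, field, PatternConfig(r_merge=10.0))
        assert len(few) == 1


class TestClassifyMode:
    def test_class_vocabulary(self):
        assert classify_mode([]) == "none"
        assert classify_mode([_spot(0, 5, "tip")]) == "elongation"
        assert classify_mode([_spot(0, 5, "tip"),
                              _spot(1.5, 2, "proximal")]) == "lateral"
        assert classify_mode([_spot(1, 4.5, "shoulder"),
                              _spot(-1, 4.5, "shoulder")]) == "bifurcation"
        assert classify_mode([_spot(1.5, 0.5, "proximal")]) == "none"

    def test_invariants(self):
        # lateral requires a tip spot and a non-tip spot
        spots = [_spot(0, 5, "tip"), _spot(1.5, 2, "proximal")]
        assert classify_mode(spots) == "lateral"
        zones = {s.zone for s in spots}
        assert "tip" in zones and zones != {"tip"}


class TestAxialSpacing:
    def test_equally_spaced_fixture(self):
        spots = [_spot(1.5, y, "proximal") for y in (0.0, 1.5, 3.0)]
        gaps = axial_spacing(spots)
        assert np.allclose(gaps, [1.5, 1.5])

    def test_staggered_flanks_measured_per_side(self):
        # left and right flanks interleave; the per-side reading gives the
        # true wavelength, not the interleaved half-spacing
        spots = ([_spot(1.5, y, "proximal") for y in (0.0, 3.0)]
                 + [_spot(-1.5, y, "proximal") for y in (1.5, 4.5)])
        gaps = axial_spacing(spots)
        assert np.allclose(gaps, [3.0, 3.0])

    def test_fewer_than_two_sites(self):
        assert len(axial_spacing([_spot(1, 1, "proximal")])) == 0


class TestBranchEvents:
    def test_static_steady_trajectory_has_no_late_events(self):
        mesh, field, _ = make_fixture("gaussian_spots_field", seed=1)
        traj = [FieldState(f=field.copy(), s=field, p=field, t=t, mesh=mesh)
                for t in np.linspace(0, 50, 26)]
        events = branch_events(traj)
        assert all(e.t <= 2.0 for e in events)  # only establishment events

    def test_new_spot_is_detected_with_position_and_tip(self):
        mesh, field, centers = make_fixture("gaussian_spots_field", seed=1)
        extra = np.exp(-((mesh.points - [1.6, 2.2]) ** 2).sum(axis=1)
                       / (2 * 0.25 ** 2))
        traj = []
        for t in np.linspace(0, 50, 26):
            fld = field + (extra if t > 25 else 0.0)
            traj.append(FieldState(f=fld, s=fld, p=fld, t=t, mesh=mesh))
        events = branch_events(traj)
        late = [e for e in events if e.t > 20]
        assert len(late) == 1
        assert np.hypot(late[0].x - 1.6, late[0].y - 2.2) < 0.3
        assert late[0].tip_y == pytest.approx(mesh.h + 2.0)  # apex of mesenchyme cap


def test_analyze_reports_config_with_result():
    mesh, field, _ = make_fixture("gaussian_spots_field", seed=1)
    state = FieldState(f=field, s=field, p=field, t=0.0, mesh=mesh)
    rep = analyze(state, PatternConfig(theta_rel=0.2))
    assert rep.config.theta_rel == 0.2
    assert rep.n_spots >= 2
    d = rep.to_dict()
    assert d["class"] == rep.pattern_class
    assert len(d["spots"]) == rep.n_spots
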
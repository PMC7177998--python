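"""Rest-point enumeration, Jacobian, eigenvalues and stability conditions."""

import numpy as np
import pytest
from scipy.optimize import root

from agrigame import (
    ContractViolationError,
    EquilibriumPoint,
    MixedState,
    all_equilibria,
    aux_constants,
    check_conditions,
    classify,
    condition_values,
    edge_equilibria,
    integrate,
    interior_equilibria,
    jacobian,
    vector_field,
    vertex_eigenvalues,
    vertex_equilibria,
)
from agrigame.dynamics import IntegrationSettings, VERTEX_LABELS, limit_state
from agrigame.model import _geh
from agrigame.sampling import random_parameters, sample_parameters

from conftest import random_state


def numeric_jacobian(params, state, h=1e-6):
    J = np.zeros((3, 3))
    base = np.array(state)
    for j in range(3):
        up, dn = base.copy(), base.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (vector_field(params, tuple(up)) - vector_field(params, tuple(dn))) / (2 * h)
    return J


class TestVertexEnumeration:
    def test_exactly_eight_corners_with_canonical_labels(self):
        points = vertex_equilibria()
        assert len(points) == 8
        by_label = {p.label: p.coords for p in points}
        assert by_label["E1"] == (0.0, 0.0, 0.0)
        assert by_label["E8"] == (1.0, 1.0, 1.0)
        assert all(set(c) <= {0.0, 1.0} for c in by_label.values())

    def test_corners_are_rest_points_for_any_parameters(self, rng):
        p = random_parameters(rng)
        for point in vertex_equilibria():
            assert np.all(vector_field(p, point.coords) == 0.0)


class TestJacobian:
    def test_matches_finite_differences(self, rng):
        for _ in range(100):
            p = random_parameters(rng)
            s = random_state(rng)
            J = jacobian(p, s)
            assert np.allclose(J, numeric_jacobian(p, s.as_tuple()), atol=1e-6)

    def test_diagonal_at_operator_only_corner(self, rng):
        """At (0,1,0) the Jacobian is diag(-a We, a(Ce-dSe-kebe), D(1-a))."""
        p = random_parameters(rng)
        a, D = p.alpha, p.dSh - p.Ch + p.khbh
        J = jacobian(p, (0.0, 1.0, 0.0))
        assert np.allclose(J, np.diag([-a * p.We, a * (p.Ce - p.dSe - p.kebe), D * (1 - a)]))

    def test_diagonal_at_origin(self, rng):
        p = random_parameters(rng)
        a, D = p.alpha, p.dSh - p.Ch + p.khbh
        J = jacobian(p, (0.0, 0.0, 0.0))
        assert np.allclose(
            J, np.diag([a * p.Pe, a * (-p.Ce + p.kebe + p.dSe), D * (1 - a)])
        )

    def test_baseline_value_at_operator_only_corner(self, baseline):
        assert np.allclose(
            jacobian(baseline, (0.0, 1.0, 0.0)), np.diag([-0.05, -0.025, 0.025])
        )

    def test_vertex_closed_forms_match_numeric_eigenvalues(self, rng):
        for _ in range(1000):
            p = random_parameters(rng)
            for label, coords in VERTEX_LABELS.items():
                closed = np.sort(np.array(vertex_eigenvalues(p, label)))
                numeric = np.sort(np.linalg.eigvals(jacobian(p, coords)).real)
                assert np.allclose(closed, numeric, atol=1e-10)


class TestEdgeEquilibria:
    def test_baseline_candidates_inadmissible_as_predicted(self, baseline):
        """At the benchmark, the z=0 candidate has x=B/A=-1/6 and the y=0
        candidate has z=4/3: both off the cube."""
        by_label = {p.label: p for p in edge_equilibria(baseline)}
        assert by_label["E11"].coords[0] == pytest.approx(-1 / 6)
        assert not by_label["E11"].admissible
        assert by_label["E10"].coords[2] == pytest.approx(4 / 3)
        assert not by_label["E10"].admissible

    def test_admissible_candidates_are_rest_points(self, rng):
        """Sampled admissible edge points zero the replicator field and are
        confirmed by an independent multivariate root-finder."""
        found = 0
        confirmed = 0
        for _ in range(300):
            p = random_parameters(rng)
            for point in edge_equilibria(p):
                if not point.admissible:
                    continue
                found += 1
                assert np.linalg.norm(vector_field(p, point.coords)) < 1e-9
                pinned = [i for i, v in enumerate(point.coords) if v in (0.0, 1.0)]
                free = [i for i in range(3) if i not in pinned]

                def residual(free_vals):
                    full = list(point.coords)
                    for i, v in zip(free, free_vals):
                        full[i] = v
                    geh = _geh(p, *full)
                    return [geh[i] for i in free]

                start = np.array([point.coords[i] for i in free]) + 0.01
                sol = root(residual, x0=start, tol=1e-12)
                if sol.success:  # reduced system can be near-singular; skip then
                    assert np.allclose(sol.x, [point.coords[i] for i in free], atol=1e-7)
                    confirmed += 1
        assert found >= 10  # the sweep actually exercised admissible cases
        assert confirmed >= 5


class TestInteriorEquilibria:
    def test_negative_discriminant_gives_empty_set(self, rng):
        for _ in range(2000):
            p = random_parameters(rng)
            if aux_constants(p).F is None:
                assert interior_equilibria(p) == []
                break
        else:
            pytest.fail("no negative-discriminant draw found")

    def test_roots_zero_all_three_drivers(self, rng):
        checked = 0
        for _ in range(500):
            p = random_parameters(rng)
            for point in interior_equilibria(p):
                checked += 1
                assert np.max(np.abs(_geh(p, *point.coords))) < 1e-9
        assert checked >= 100

    def test_closed_form_agrees_with_root_finder(self, rng):
        """Admissible interior roots match an independent solver to 1e-6."""
        matched = 0
        for _ in range(3000):
            p = random_parameters(rng)
            for point in interior_equilibria(p, cross_check=False):
                if not point.admissible:
                    continue
                sol = root(lambda v: _geh(p, *v), x0=np.array(point.coords) + 0.003, tol=1e-13)
                if sol.success:
                    assert np.allclose(sol.x, point.coords, atol=1e-6)
                    matched += 1
        assert matched >= 5

    def test_baseline_interior_candidates_flagged(self, baseline):
        for point in interior_equilibria(baseline):
            inside = all(0 < c < 1 for c in point.coords)
            assert point.admissible == inside


class TestClassification:
    def test_full_cooperation_stable_at_baseline(self, baseline):
        point = EquilibriumPoint(coords=(1.0, 1.0, 1.0), kind="vertex", label="E8")
        result = classify(baseline, point)
        eig = sorted(ev.real for ev in result.eigenvalues)
        assert eig == pytest.approx([-0.4, -0.3, -0.075])
        assert result.classification == "asymptotically_stable"
        assert result.matched_condition == 6

    def test_origin_unstable_whenever_fines_are_positive(self, rng):
        for _ in range(50):
            p = random_parameters(rng)
            point = EquilibriumPoint(coords=(0.0, 0.0, 0.0), kind="vertex", label="E1")
            assert classify(p, point).classification == "unstable"

    def test_government_and_operator_only_corner_unstable(self, rng):
        """(1,1,0) always carries the positive eigenvalue alpha*We."""
        for _ in range(50):
            p = random_parameters(rng)
            point = EquilibriumPoint(coords=(1.0, 1.0, 0.0), kind="vertex", label="E5")
            assert classify(p, point).classification == "unstable"

    def test_non_rest_point_rejected(self, baseline):
        point = EquilibriumPoint(coords=(0.4, 0.2, 0.3), kind="interior", label=None)
        with pytest.raises(ContractViolationError):
            classify(baseline, point)


class TestConditions:
    def test_baseline_satisfies_full_cooperation_condition(self, baseline):
        assert 6 in check_conditions(baseline)
        assert all(v < 0 for v in condition_values(baseline, 6))

    def test_low_reward_switches_to_government_dropout_condition(self, baseline):
        conds = check_conditions(baseline.replace(dSg=0.01))
        assert 5 in conds and 6 not in conds
        v = condition_values(baseline.replace(dSg=0.01), 5)
        assert v[0] == pytest.approx(0.01 - 0.05 - 0.05)
        assert v[1] == pytest.approx(-0.3)

    def test_high_cost_switches_to_producer_defection_condition(self, baseline):
        p = baseline.replace(Ce=0.9, Ch=0.8)
        conds = check_conditions(p)
        assert 3 in conds
        assert condition_values(p, 3) == pytest.approx((-0.1, -0.25, -0.175))

    def test_classification_condition_coherence(self, rng):
        """A corner with a condition label is asymptotically stable iff its
        condition inequalities hold."""
        from agrigame.equilibria import CONDITION_OF_POINT

        for _ in range(200):
            p = random_parameters(rng)
            conds = check_conditions(p)
            for point in vertex_equilibria():
                if point.label not in CONDITION_OF_POINT:
                    continue
                stable = classify(p, point).classification == "asymptotically_stable"
                assert stable == (CONDITION_OF_POINT[point.label] in conds)

    @pytest.mark.parametrize(
        "condition, label",
        [(1, "E2"), (2, "E3"), (3, "E4"), (4, "E6"), (5, "E7"), (6, "E8")],
    )
    def test_local_convergence_under_sampled_conditions(self, condition, label):
        """Starts within 0.05 of the predicted corner converge to it when the
        corner's stability condition holds."""
        vertex = VERTEX_LABELS[label]
        for seed in (1, 2, 3):
            p = sample_parameters(condition, seed=seed)
            start = MixedState(*(abs(v - 0.05) for v in vertex))
            traj = integrate(p, start, IntegrationSettings(t_end=4000))
            res = limit_state(traj, vertex_tol=1e-3)
            assert res.matched_vertex == label


def test_stability_report_covers_all_candidates(baseline):
    from agrigame import stability_report

    df = stability_report(baseline)
    assert set(df[df.kind == "vertex"].label) == set(VERTEX_LABELS)
    assert len(df) == len(all_equilibria(baseline))
    stable = df[df.classification == "asymptotically_stable"]
    assert list(stable.label) == ["E8"]
    assert list(stable.condition) == [6]
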
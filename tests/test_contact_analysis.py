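"""Unit tests for the contact statistics operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prkap.cg_builder import BindingSiteSet, RegionAnnotation
from prkap.contact_analysis import (
    binding_probability,
    compute_contact_results,
    contact_sites,
    frame_contacts,
    ncpr_contact_regression,
    region_contact_counts,
    residue_contact_probability,
    scalar_uncertainty,
    shared_binding_sites,
    time_averaged_contacts,
)
from prkap.synthetic_data import generate_fixture_trajectory

from conftest import brute_force_contacts


class TestFrameContacts:
    def test_single_contact(self):
        frame = np.zeros((3, 3))
        frame[0] = [10.0, 10, 10]  # receptor
        frame[1] = [10.5, 10, 10]  # probe in contact
        frame[2] = [40.0, 40, 40]  # probe far
        count, pf, rf = frame_contacts(frame, 100.0, probe_idx=[1, 2],
                                       receptor_idx=[0])
        assert count == 1
        assert pf.tolist() == [True, False]
        assert rf.tolist() == [True]

    def test_no_contacts(self):
        frame = np.array([[10.0, 10, 10], [15.0, 10, 10]])
        count, pf, rf = frame_contacts(frame, 100.0, [1], [0])
        assert count == 0
        assert not pf.any() and not rf.any()

    def test_minimum_image_across_boundary(self):
        box = 20.0
        frame = np.array([[0.2, 10.0, 10.0], [19.9, 10.0, 10.0]])
        count, _pf, _rf = frame_contacts(frame, box, [1], [0])
        assert count == 1  # separation 0.3 nm through the boundary

    def test_matches_brute_force_on_random_frames(self, rng):
        box = 8.0
        for _ in range(25):
            frame = rng.uniform(0, box, (70, 3))
            probe_idx = np.arange(40, 70)
            receptor_idx = np.arange(40)
            c1, pf1, rf1 = frame_contacts(frame, box, probe_idx, receptor_idx)
            c2, pf2, rf2 = brute_force_contacts(frame, box, probe_idx,
                                                receptor_idx)
            assert c1 == c2
            np.testing.assert_array_equal(pf1, pf2)
            np.testing.assert_array_equal(rf1, rf2)

    def test_missing_role_is_error(self):
        with pytest.raises(ValueError):
            frame_contacts(np.zeros((2, 3)), 10.0, [], [0])


class TestTimeAveragedContacts:
    def test_constant_contacts(self):
        script = [{p: p for p in range(5)}] * 4  # 5 contacts every frame
        traj = generate_fixture_trajectory(script, n_probe=14, n_receptor=100)
        ct, ct_norm = time_averaged_contacts(traj, equilibration_fraction=0.0)
        assert ct == 5.0
        assert ct_norm == pytest.approx(5.0 / (100 * 14))

    def test_mean_of_two_frames(self):
        script = [{}, {p: p for p in range(10)}]
        traj = generate_fixture_trajectory(script, n_probe=14, n_receptor=100)
        ct, _ = time_averaged_contacts(traj, equilibration_fraction=0.0)
        assert ct == 5.0

    def test_scripted_fixture_hand_computed(self, rng):
        # random script; oracle = mean of per-frame pair counts
        script = []
        for _ in range(12):
            k = int(rng.integers(0, 14))
            probes = rng.choice(14, size=k, replace=False)
            script.append({int(p): int(rng.integers(0, 100)) for p in probes})
        traj = generate_fixture_trajectory(script, n_probe=14, n_receptor=100)
        ct, ct_norm = time_averaged_contacts(traj, equilibration_fraction=0.0)
        expected = np.mean([len(s) for s in script])
        assert ct == pytest.approx(expected)
        assert ct_norm == pytest.approx(expected / (100 * 14))

    def test_equilibration_discard(self):
        # 10 frames at 20% -> first 2 discarded
        script = [{0: 0}] * 2 + [{}] * 8
        traj = generate_fixture_trajectory(script, 5, 5)
        ct, _ = time_averaged_contacts(traj, equilibration_fraction=0.2)
        assert ct == 0.0
        # at least one production frame always remains for valid fractions
        single = generate_fixture_trajectory([{}], 5, 5)
        assert single.positions[single.production_slice(0.99)].shape[0] == 1


class TestBindingProbability:
    def test_always_bound(self):
        script = [{p: p for p in range(10)}] * 6
        traj = generate_fixture_trajectory(script, n_probe=14, n_receptor=20)
        assert binding_probability(traj, equilibration_fraction=0.0) == 1.0

    def test_never_bound(self):
        traj = generate_fixture_trajectory([{}] * 6, n_probe=14, n_receptor=20)
        assert binding_probability(traj, equilibration_fraction=0.0) == 0.0

    def test_strict_threshold_pr7(self):
        """14 residues: 1 in contact (1 <= 1.4) unbound, 2 (> 1.4) bound."""
        one = generate_fixture_trajectory([{0: 0}], n_probe=14, n_receptor=20)
        two = generate_fixture_trajectory([{0: 0, 1: 1}], n_probe=14,
                                          n_receptor=20)
        assert binding_probability(one, equilibration_fraction=0.0) == 0.0
        assert binding_probability(two, equilibration_fraction=0.0) == 1.0

    def test_boundary_exact_ten_percent_unbound(self):
        """Exactly 10% in contact is NOT bound (strict inequality)."""
        traj = generate_fixture_trajectory([{0: 0}], n_probe=10, n_receptor=20)
        assert binding_probability(traj, equilibration_fraction=0.0) == 0.0


class TestResidueContactProbability:
    def test_always_in_contact(self):
        script = [{0: 3}] * 8
        traj = generate_fixture_trajectory(script, n_probe=5, n_receptor=10)
        profile = residue_contact_probability(traj, equilibration_fraction=0.0)
        assert profile[3] == 1.0
        assert profile.sum() == 1.0

    def test_alternating_half(self):
        script = [{0: 3}, {}] * 5
        traj = generate_fixture_trajectory(script, n_probe=5, n_receptor=10)
        profile = residue_contact_probability(traj, equilibration_fraction=0.0)
        assert profile[3] == 0.5

    def test_matches_per_residue_recount(self, rng):
        script = [{int(p): int(rng.integers(0, 8)) for p in
                   rng.choice(6, size=int(rng.integers(0, 6)), replace=False)}
                  for _ in range(15)]
        traj = generate_fixture_trajectory(script, n_probe=6, n_receptor=8)
        profile = residue_contact_probability(traj, equilibration_fraction=0.0)
        expected = np.zeros(8)
        for s in script:
            for r in set(s.values()):
                expected[r] += 1
        np.testing.assert_allclose(profile, expected / len(script))


class TestContactSites:
    def test_strict_boundary(self):
        sites = contact_sites(np.array([0.05, 0.10, 0.11]))
        assert sites == frozenset({2})

    def test_all_zero(self):
        assert contact_sites(np.zeros(10)) == frozenset()

    def test_matches_filter_oracle(self, rng):
        profile = rng.random(1000)
        sites = contact_sites(profile, threshold=0.37)
        expected = frozenset(i for i, p in enumerate(profile) if p > 0.37)
        assert sites == expected


class TestRegionCounts:
    def test_basic_example(self):
        ann = RegionAnnotation(spans=[(0, 3, 1, "A"), (4, 7, 1, "B"),
                                      (8, 11, 1, "linker")])
        counts = region_contact_counts({2, 4, 8}, ann)
        assert counts == {"A": 1, "B": 1, "linker": 1, "unannotated": 0}

    def test_empty_sites(self):
        ann = RegionAnnotation(spans=[(0, 3, 1, "A")])
        counts = region_contact_counts(set(), ann)
        assert sum(counts.values()) == 0

    def test_unannotated_reported_separately(self):
        ann = RegionAnnotation(spans=[(0, 3, 1, "A")])
        counts = region_contact_counts({1, 10}, ann)
        assert counts["A"] == 1
        assert counts["unannotated"] == 1

    def test_matches_interval_membership_oracle(self, rng, toy_receptor):
        _model, ann, _sites = toy_receptor
        n = _model.n_beads
        picked = set(int(i) for i in rng.choice(n, size=40, replace=False))
        counts = region_contact_counts(picked, ann)
        expected = {"A": 0, "B": 0, "linker": 0, "unannotated": 0}
        for i in picked:
            hit = None
            for start, end, _h, label in ann.spans:
                if start <= i <= end:
                    hit = label
                    break
            expected[hit if hit else "unannotated"] += 1
        assert counts == expected


class TestSharedSites:
    def test_intersection(self):
        sites = BindingSiteSet(rangtp={5, 9, 12})
        out = shared_binding_sites({3, 5, 9}, sites)
        assert out["rangtp"] == 2

    def test_absent_class_is_none_not_zero(self):
        sites = BindingSiteSet(cargo={1})
        out = shared_binding_sites({1}, sites)
        assert out["cargo"] == 1
        assert out["ibb"] is None
        assert out["fg_nup"] is None

    def test_matches_set_oracle(self, rng):
        a = frozenset(int(i) for i in rng.choice(200, 50, replace=False))
        b = frozenset(int(i) for i in rng.choice(200, 30, replace=False))
        out = shared_binding_sites(a, BindingSiteSet(cargo=b))
        assert out["cargo"] == len(a & b)
        assert out["cargo"] <= min(len(a), len(b))


class TestScalarUncertainty:
    def test_identical_blocks(self):
        assert scalar_uncertainty([3.0, 3.0, 3.0]) == 0.0

    def test_two_blocks_closed_form(self):
        assert scalar_uncertainty([0.0, 2.0]) == pytest.approx(0.5 * np.sqrt(2.0))

    def test_matches_textbook_formula(self, rng):
        vals = rng.normal(0, 1, 10)
        assert scalar_uncertainty(vals) == pytest.approx(
            0.5 * np.sqrt(((vals - vals.mean())**2).sum() / 9))

    def test_single_block_error(self):
        with pytest.raises(ValueError):
            scalar_uncertainty([1.0])


class TestRegression:
    def test_collinear(self):
        pts = [(-0.1, 1.0), (-0.05, 0.5), (0.0, 0.0)]
        slope, intercept, r = ncpr_contact_regression(pts)
        assert slope == pytest.approx(-10.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert abs(r) == pytest.approx(1.0)

    def test_symmetric_clusters_zero_slope(self):
        pts = [(-1.0, 0.0), (-1.0, 2.0), (1.0, 0.0), (1.0, 2.0)]
        slope, _i, _r = ncpr_contact_regression(pts)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        slope, intercept, r = ncpr_contact_regression(zip(x, y))
        sxx = ((x - x.mean())**2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert slope == pytest.approx(sxy / sxx)
        assert intercept == pytest.approx(y.mean() - slope * x.mean())
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_degenerate_x_is_error(self):
        with pytest.raises(ValueError):
            ncpr_contact_regression([(1.0, 0.0), (1.0, 1.0), (1.0, 2.0)])

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            ncpr_contact_regression([(0.0, 0.0), (1.0, 1.0)])


class TestComputeContactResults:
    def _random_script(self, rng, frames, n_probe, n_rec):
        return [{int(p): int(rng.integers(0, n_rec)) for p in
                 rng.choice(n_probe, size=int(rng.integers(0, n_probe + 1)),
                            replace=False)}
                for _ in range(frames)]

    def test_invariants_on_random_fixture(self, rng):
        n_probe, n_rec = 14, 40
        script = self._random_script(rng, 30, n_probe, n_rec)
        traj = generate_fixture_trajectory(script, n_probe, n_rec)
        ann = RegionAnnotation(spans=[(0, 9, 1, "A"), (10, 19, 1, "B"),
                                      (20, 39, 1, "linker")])
        sites = BindingSiteSet(cargo={1, 2, 3}, rangtp={20, 25})
        res = compute_contact_results(traj, ann, sites,
                                      equilibration_fraction=0.0)
        res.validate()
        region_sum = sum(res.ncontact_by_region[k]
                         for k in ("A", "B", "linker", "unannotated"))
        assert region_sum == len(res.contact_site_set)
        for cls, n_shared in res.nshared_by_class.items():
            known = getattr(sites, cls)
            if known is None:
                assert n_shared is None
            else:
                assert n_shared <= min(len(res.contact_site_set), len(known))

    def test_closed_forms_from_script(self, rng):
        n_probe, n_rec = 10, 25
        script = self._random_script(rng, 20, n_probe, n_rec)
        traj = generate_fixture_trajectory(script, n_probe, n_rec)
        res = compute_contact_results(traj, equilibration_fraction=0.0)
        assert res.ct == pytest.approx(np.mean([len(s) for s in script]))
        bound = [len(s) > 0.1 * n_probe for s in script]
        assert res.pb == pytest.approx(np.mean(bound))
        expected_profile = np.zeros(n_rec)
        for s in script:
            for rr in set(s.values()):
                expected_profile[rr] += 1
        np.testing.assert_allclose(res.residue_profile,
                                   expected_profile / len(script))

    def test_ct_invariant_under_bead_relabeling(self, rng):
        """Normalised Ct does not depend on the ordering of receptor beads."""
        n_probe, n_rec = 8, 20
        script = self._random_script(rng, 12, n_probe, n_rec)
        perm = rng.permutation(n_rec)
        relabeled = [{p: int(perm[r]) for p, r in s.items()} for s in script]
        t1 = generate_fixture_trajectory(script, n_probe, n_rec)
        t2 = generate_fixture_trajectory(relabeled, n_probe, n_rec)
        r1 = compute_contact_results(t1, equilibration_fraction=0.0)
        r2 = compute_contact_results(t2, equilibration_fraction=0.0)
        assert r1.ct_normalized == pytest.approx(r2.ct_normalized)
        assert r1.pb == r2.pb

    @given(st.lists(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 14)),
                             max_size=10, unique_by=lambda t: t[0]),
                    min_size=1, max_size=12))
    @settings(max_examples=25, deadline=None)
    def test_property_script_is_its_own_oracle(self, script):
        traj = generate_fixture_trajectory(script, n_probe=10, n_receptor=15)
        res = compute_contact_results(traj, equilibration_fraction=0.0)
        counts = [len(s) for s in script]
        assert res.ct == pytest.approx(np.mean(counts))
        assert 0.0 <= res.pb <= 1.0
        assert res.pb == pytest.approx(
            np.mean([c > 1.0 for c in counts]))  # 10% of 10 residues, strict


class TestTsvOutputs:
    def test_one_tsv_per_statistic(self, tmp_path, rng):
        script = [{0: 2, 1: 3}] * 10
        traj = generate_fixture_trajectory(script, n_probe=5, n_receptor=10)
        ann = RegionAnnotation(spans=[(0, 4, 1, "A"), (5, 9, 1, "B")])
        sites = BindingSiteSet(cargo={2, 3})
        res = compute_contact_results(traj, ann, sites,
                                      equilibration_fraction=0.0)
        res.to_tsv_dir(tmp_path)
        for f in ("scalars.tsv", "residue_profile.tsv", "contact_sites.tsv",
                  "ncontact_by_region.tsv", "nshared_by_class.tsv"):
            assert (tmp_path / f).exists(), f
        # contact sites written 1-based
        lines = (tmp_path / "contact_sites.tsv").read_text().splitlines()
        assert lines[1:] == ["3", "4"]
        shared = (tmp_path / "nshared_by_class.tsv").read_text()
        assert "cargo\t2" in shared
        assert "ibb\t-" in shared  # absent class marked "-"
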
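"""Superimposition: centroid size, GPA, local alignment, species means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import orthogonal_procrustes

from allomorph.io import LandmarkDataset, LandmarkScheme
from allomorph.superimpose import (
    centroid_size,
    gpa,
    local_superimpose,
    species_means,
)
from allomorph.simulate import make_landmark_fixture


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q


def _dataset(coords, scheme=None):
    n, k, _ = coords.shape
    if scheme is None:
        labels = tuple(f"p{i}" for i in range(k))
        scheme = LandmarkScheme(
            labels, {p: "all" for p in labels}, {p: False for p in labels}
        )
    meta = pd.DataFrame({"specimen": [f"s{i}" for i in range(n)]})
    return LandmarkDataset(coords, scheme, meta)


class TestCentroidSize:
    def test_square_configuration(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(8))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_translation_invariance_and_homogeneity(self, seed, shift, scale):
        x = np.random.default_rng(seed).normal(size=(7, 3))
        base = centroid_size(x)
        assert centroid_size(x + shift) == pytest.approx(base, rel=1e-9)
        assert centroid_size(x * scale) == pytest.approx(base * scale, rel=1e-9)

    def test_coincident_points_give_zero(self):
        assert centroid_size(np.ones((5, 3))) == 0.0


class TestGPA:
    def test_similarity_transformed_copy_aligns_exactly(self, rng):
        x = rng.normal(size=(8, 3))
        y = 2.5 * (x @ _random_rotation(rng)) + np.array([3.0, -1.0, 7.0])
        aligned = gpa(_dataset(np.stack([x, y])))
        d = np.linalg.norm(aligned.aligned[0] - aligned.aligned[1])
        assert d < 1e-7

    def test_duplicated_configuration_zero_variance(self, rng):
        x = rng.normal(size=(6, 3))
        aligned = gpa(_dataset(np.stack([x] * 5)))
        ss = ((aligned.aligned - aligned.consensus) ** 2).sum()
        assert ss < 1e-20
        np.testing.assert_allclose(aligned.aligned[0], aligned.consensus, atol=1e-12)

    def test_unit_size_and_centering(self, rng):
        aligned = gpa(_dataset(rng.normal(size=(4, 6, 3))))
        for cfg in aligned.aligned:
            np.testing.assert_allclose(cfg.mean(axis=0), 0, atol=1e-12)
            assert centroid_size(cfg) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            aligned.log_centroid_size, np.log(aligned.centroid_size)
        )

    def test_consensus_matches_alternating_oracle(self, rng):
        """Independent alternating-least-squares superimposition agrees.

        The oracle centres and unit-scales every configuration, then
        alternates orthogonal-Procrustes rotations to the running mean
        until the fit stops improving; consensus shapes are compared after
        optimally rotating one onto the other.
        """
        base = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.4, 0.9, 0.0]]
        )
        coords = np.stack(
            [base + 0.02 * rng.normal(size=(3, 3)) for _ in range(5)]
        )
        aligned = gpa(_dataset(coords), tol=1e-14, max_iter=500)

        # oracle: independent alternating minimization of sum ||X_i - M||^2
        xs = []
        for c in coords:
            c = c - c.mean(axis=0)
            xs.append(c / np.linalg.norm(c))
        m = xs[0]
        for _ in range(500):
            xs = [x @ orthogonal_procrustes(x, m)[0] for x in xs]
            new_m = np.mean(xs, axis=0)
            if np.linalg.norm(new_m - m) < 1e-14:
                m = new_m
                break
            m = new_m

        r, _ = orthogonal_procrustes(m, aligned.consensus)
        assert np.linalg.norm(m @ r - aligned.consensus) < 1e-6

    def test_deviation_ss_non_increasing_over_iterations(self, rng):
        coords = rng.normal(size=(6, 5, 3))
        data = _dataset(coords)
        ss = []
        for it in range(1, 8):
            aligned = gpa(data, tol=0.0, max_iter=it)
            ss.append(((aligned.aligned - aligned.consensus) ** 2).sum())
        diffs = np.diff(ss)
        assert np.all(diffs <= 1e-12)

    def test_invariance_to_common_similarity_transform(self, rng):
        coords = rng.normal(size=(5, 6, 3))
        q = _random_rotation(rng)
        moved = 3.0 * coords @ q + np.array([1.0, 2.0, 3.0])
        a1 = gpa(_dataset(coords), tol=1e-14, max_iter=300)
        a2 = gpa(_dataset(moved), tol=1e-14, max_iter=300)
        # solutions agree up to one global rotation
        r, _ = orthogonal_procrustes(
            a1.aligned.reshape(-1, 3), a2.aligned.reshape(-1, 3)
        )
        np.testing.assert_allclose(
            a1.aligned.reshape(-1, 3) @ r, a2.aligned.reshape(-1, 3), atol=1e-7
        )
        np.testing.assert_allclose(a2.centroid_size, 3.0 * a1.centroid_size, rtol=1e-9)

    def test_degenerate_configuration_rejected(self):
        coords = np.zeros((3, 4, 3))
        coords[1] = np.random.default_rng(0).normal(size=(4, 3))
        coords[2] = np.random.default_rng(1).normal(size=(4, 3))
        with pytest.raises(ValueError, match="degenerate"):
            gpa(_dataset(coords))

    def test_collinear_configuration_rejected(self, rng):
        line = np.zeros((4, 3))
        line[:, 0] = [0, 1, 2, 3]
        coords = np.stack([line, rng.normal(size=(4, 3)), rng.normal(size=(4, 3))])
        with pytest.raises(ValueError, match="rank-deficient"):
            gpa(_dataset(coords))


class TestLocalSuperimposition:
    def test_single_subset_equals_whole_gpa(self, rng):
        fixture = make_landmark_fixture(n_specimens=6, k=8, seed=3, n_bones=1)
        whole = gpa(fixture)
        local = local_superimpose(fixture)
        assert list(local) == [fixture.scheme.bones[0]]
        np.testing.assert_allclose(
            local[fixture.scheme.bones[0]].aligned, whole.aligned, atol=1e-12
        )

    def test_independently_rotated_rigid_bodies(self, rng):
        """Per-bone variance vanishes while whole-configuration variance stays.

        Two rigid point sets are each given an independent random rotation
        per specimen (articulation): locally each bone is one fixed shape,
        but the combined configuration varies.
        """
        bone_a = rng.normal(size=(5, 3))
        bone_b = rng.normal(size=(5, 3)) + np.array([4.0, 0.0, 0.0])
        n = 8
        coords = np.empty((n, 10, 3))
        for i in range(n):
            coords[i, :5] = bone_a @ _random_rotation(rng)
            coords[i, 5:] = bone_b @ _random_rotation(rng) + np.array([4.0, 0, 0])
        labels = tuple(f"p{i}" for i in range(10))
        scheme = LandmarkScheme(
            labels,
            {p: ("A" if i < 5 else "B") for i, p in enumerate(labels)},
            {p: False for p in labels},
        )
        data = _dataset(coords, scheme)
        local = local_superimpose(data, tol=1e-12, max_iter=500)
        whole = gpa(data, tol=1e-12, max_iter=500)

        def proc_var(a):
            return ((a.aligned - a.consensus) ** 2).sum() / a.n_specimens

        assert proc_var(local["A"]) < 1e-10
        assert proc_var(local["B"]) < 1e-10
        assert proc_var(whole) > 1e-3

    def test_small_bone_skipped_with_warning(self, toy_dataset, caplog):
        # "cranium" has a single point -> cannot be superimposed
        out = local_superimpose(toy_dataset)
        assert "cranium" not in out
        assert "jaw" in out

    def test_full_scale_scheme_units(self):
        fixture = make_landmark_fixture(n_specimens=3, k=200, seed=1)
        assert fixture.scheme.n_points == 200
        assert len(fixture.scheme.bones) == 10
        out = local_superimpose(fixture)
        assert len(out) == 10  # plus the whole configuration analysed separately


class TestSpeciesMeans:
    def _aligned(self, rng, species, cs):
        n = len(species)
        fixture = make_landmark_fixture(n_specimens=n, k=5, seed=9, n_bones=1)
        aligned = gpa(fixture)
        aligned.specimens["species"] = species
        aligned.centroid_size = np.asarray(cs, float)
        aligned.log_centroid_size = np.log(aligned.centroid_size)
        return aligned

    def test_single_specimen_species_is_identity(self, rng):
        aligned = self._aligned(rng, ["x", "y", "z"], [1.0, 2.0, 3.0])
        means = species_means(aligned)
        assert means.n_specimens == 3
        np.testing.assert_allclose(means.aligned, aligned.aligned[[0, 1, 2]])

    def test_cs_arithmetic_mean_and_log_of_mean(self, rng):
        aligned = self._aligned(rng, ["x", "x", "y"], [2.0, 4.0, 5.0])
        means = species_means(aligned)
        i = list(means.specimens["species"]).index("x")
        assert means.centroid_size[i] == pytest.approx(3.0)
        assert means.log_centroid_size[i] == pytest.approx(np.log(3.0))

    def test_sorted_deterministic_order(self, rng):
        aligned = self._aligned(rng, ["zeta", "alpha", "mid"], [1, 1, 1])
        means = species_means(aligned)
        assert list(means.specimens["species"]) == ["alpha", "mid", "zeta"]
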
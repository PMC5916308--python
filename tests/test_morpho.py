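"""Semilandmarks, Procrustes superimposition, relative warps, broken stick."""

import numpy as np
import pandas as pd
import pytest

from karstcomm import ValidationError, morpho


def _rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _circle_outline(radius=1.0, n=1000, start=0):
    theta = 2 * np.pi * np.arange(n) / n
    return morpho.Outline(
        vertices=np.column_stack([radius * np.cos(theta), radius * np.sin(theta)]),
        start_index=start,
    )


def _random_config(rng, k=12, spec_id="s"):
    return morpho.LandmarkConfiguration(specimen_id=spec_id, coords=rng.normal(size=(k, 2)))


class TestResample:
    def test_circle_gives_equal_angles_and_radius(self):
        outline = _circle_outline(radius=3.0)
        cfg = morpho.resample_semilandmarks(outline, k=8)
        radii = np.linalg.norm(cfg.coords, axis=1)
        assert np.all(np.abs(radii - 3.0) < 1e-3 * 3.0)
        angles = np.unwrap(np.arctan2(cfg.coords[:, 1], cfg.coords[:, 0]))
        steps = np.degrees(np.diff(angles))
        assert np.all(np.abs(steps - 45.0) < 0.1)

    def test_unit_square_corners(self):
        square = morpho.Outline(
            vertices=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]), start_index=0
        )
        cfg = morpho.resample_semilandmarks(square, k=4)
        np.testing.assert_allclose(
            cfg.coords, [[0, 0], [1, 0], [1, 1], [0, 1]], atol=1e-12
        )

    def test_default_k_is_200(self):
        cfg = morpho.resample_semilandmarks(_circle_outline())
        assert cfg.k == 200

    def test_first_point_at_start_vertex(self):
        outline = _circle_outline(n=100, start=37)
        cfg = morpho.resample_semilandmarks(outline, k=50)
        np.testing.assert_allclose(cfg.coords[0], outline.vertices[37], atol=1e-12)

    def test_clockwise_outline_normalized(self):
        ccw = _circle_outline(n=200)
        cw = morpho.Outline(vertices=ccw.vertices[::-1], start_index=199)
        a = morpho.resample_semilandmarks(ccw, k=20)
        b = morpho.resample_semilandmarks(cw, k=20)
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    def test_points_lie_on_polygon(self, rng):
        r = 1.0 + 0.2 * np.cos(3 * 2 * np.pi * np.arange(300) / 300)
        theta = 2 * np.pi * np.arange(300) / 300
        outline = morpho.Outline(
            vertices=np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        )
        cfg = morpho.resample_semilandmarks(outline, k=97)
        verts = outline.vertices
        closed = np.vstack([verts, verts[:1]])
        for p in cfg.coords:
            seg = closed[1:] - closed[:-1]
            rel = p - closed[:-1]
            t = np.clip((rel * seg).sum(1) / (seg * seg).sum(1), 0, 1)
            dist = np.linalg.norm(rel - t[:, None] * seg, axis=1).min()
            assert dist < 1e-9 * outline.perimeter

    def test_degenerate_outline_rejected(self):
        with pytest.raises(ValidationError):
            morpho.Outline(vertices=np.array([[0, 0], [0, 0], [1, 1]]))


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        cfg = morpho.LandmarkConfiguration("sq", np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float))
        assert morpho.centroid_size(cfg) == pytest.approx(np.sqrt(2.0))

    def test_homogeneous_in_scale(self, rng):
        cfg = _random_config(rng)
        assert morpho.centroid_size(
            morpho.LandmarkConfiguration("x", 3.7 * cfg.coords)
        ) == pytest.approx(3.7 * morpho.centroid_size(cfg))

    def test_matches_direct_summation(self, rng):
        coords = rng.normal(size=(30, 2))
        direct = np.sqrt(sum(((p - coords.mean(0)) ** 2).sum() for p in coords))
        assert morpho.centroid_size(morpho.LandmarkConfiguration("x", coords)) == pytest.approx(direct)

    def test_identical_points_rejected(self):
        with pytest.raises(ValidationError):
            morpho.centroid_size(morpho.LandmarkConfiguration("x", np.ones((5, 2))))


class TestProcrustes:
    def test_rigid_copies_superimpose_exactly(self, rng):
        base = rng.normal(size=(20, 2))
        moved = base @ _rotation(0.8).T + np.array([5.0, -2.0])
        res = morpho.procrustes_align(
            [
                morpho.LandmarkConfiguration("a", base),
                morpho.LandmarkConfiguration("b", moved),
            ],
            keep_size=True,
        )
        rms = np.sqrt(np.mean((res.aligned[0].coords - res.aligned[1].coords) ** 2))
        assert rms < 1e-9

    def test_scaled_copy_modes(self, rng):
        base = rng.normal(size=(15, 2))
        scaled = 2.0 * (base @ _rotation(-1.1).T) + 3.0
        configs = [
            morpho.LandmarkConfiguration("a", base),
            morpho.LandmarkConfiguration("b", scaled),
        ]
        shape_only = morpho.procrustes_align(configs, keep_size=False)
        rms = np.sqrt(np.mean((shape_only.aligned[0].coords - shape_only.aligned[1].coords) ** 2))
        assert rms < 1e-9
        with_size = morpho.procrustes_align(configs, keep_size=True)
        assert with_size.centroid_sizes[1] / with_size.centroid_sizes[0] == pytest.approx(2.0)
        for cfg in shape_only.aligned:
            assert morpho.centroid_size(cfg) == pytest.approx(1.0, abs=1e-9)

    def test_two_config_residual_matches_rotation_grid_oracle(self, rng):
        a, b = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        norm = []
        for m in (a, b):
            c = m - m.mean(0)
            norm.append(c / morpho.centroid_size(morpho.LandmarkConfiguration("x", c)))
        thetas = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
        best = min(((norm[0] @ _rotation(t).T - norm[1]) ** 2).sum() for t in thetas)
        res = morpho.procrustes_align(
            [morpho.LandmarkConfiguration("a", a), morpho.LandmarkConfiguration("b", b)],
            keep_size=False,
        )
        # GPA residual sums squared deviations from the mean: half the pairwise SS
        assert res.residual == pytest.approx(best / 2, abs=1e-6)

    def test_alignment_never_increases_total_ss(self, rng):
        configs = [_random_config(rng, spec_id=f"s{i}") for i in range(10)]
        centered = [c.coords - c.coords.mean(0) for c in configs]
        scaled = [m / morpho.centroid_size(morpho.LandmarkConfiguration("x", m)) for m in centered]
        before = sum(((m - np.mean(scaled, axis=0)) ** 2).sum() for m in scaled)
        res = morpho.procrustes_align(configs, keep_size=False)
        assert res.residual <= before + 1e-9

    def test_order_invariance_of_consensus(self, rng):
        configs = [_random_config(rng, spec_id=f"s{i}") for i in range(8)]
        res1 = morpho.procrustes_align(configs, keep_size=False)
        res2 = morpho.procrustes_align(configs[::-1], keep_size=False)
        assert np.max(np.abs(res1.consensus - res2.consensus)) < 1e-6

    def test_consensus_centered_at_origin(self, rng):
        res = morpho.procrustes_align([_random_config(rng, spec_id=f"s{i}") for i in range(5)])
        np.testing.assert_allclose(res.consensus.mean(axis=0), [0, 0], atol=1e-9)

    def test_mismatched_landmark_counts_rejected(self, rng):
        with pytest.raises(ValidationError, match="landmark counts"):
            morpho.procrustes_align(
                [_random_config(rng, k=10, spec_id="a"), _random_config(rng, k=12, spec_id="b")]
            )


class TestAveraging:
    def test_identical_configs_average_to_themselves(self, rng):
        coords = rng.normal(size=(8, 2))
        aligned = [
            morpho.LandmarkConfiguration(f"s{i}", coords.copy(), aligned=True) for i in range(3)
        ]
        means = morpho.average_configuration(aligned, {f"s{i}": "g" for i in range(3)})
        np.testing.assert_allclose(means["g"].coords, coords)

    def test_mirrored_pair_averages_to_midpoint(self, rng):
        c = rng.normal(size=(8, 2))
        aligned = [
            morpho.LandmarkConfiguration("a", c + 0.5, aligned=True),
            morpho.LandmarkConfiguration("b", c - 0.5, aligned=True),
        ]
        means = morpho.average_configuration(aligned, {"a": "g", "b": "g"})
        np.testing.assert_allclose(means["g"].coords, c)

    def test_matches_per_coordinate_recomputation(self, rng):
        aligned = [
            morpho.LandmarkConfiguration(f"s{i}", rng.normal(size=(6, 2)), aligned=True)
            for i in range(7)
        ]
        groups = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(7)}
        means = morpho.average_configuration(aligned, groups)
        expected_g2 = np.mean([aligned[i].coords for i in range(4, 7)], axis=0)
        np.testing.assert_allclose(means["g2"].coords, expected_g2)

    def test_empty_group_rejected(self, rng):
        aligned = [morpho.LandmarkConfiguration("a", rng.normal(size=(5, 2)), aligned=True)]
        with pytest.raises(ValidationError, match="empty group"):
            morpho.average_configuration(aligned, {"a": "g1", "phantom": "g2"})


class TestPCA:
    def _configs_from_rows(self, rows):
        return {
            f"g{i}": morpho.LandmarkConfiguration(f"g{i}", row.reshape(-1, 2), aligned=True)
            for i, row in enumerate(rows)
        }

    def test_single_axis_variation_is_pc1_only(self):
        rows = np.zeros((4, 8))
        rows[:, 0] = [0.0, 1.0, 2.0, 3.0]
        res = morpho.pca_relative_warps(self._configs_from_rows(rows))
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_percent_variance_sums_to_100(self, rng):
        rows = rng.normal(size=(6, 10))
        res = morpho.pca_relative_warps(self._configs_from_rows(rows))
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_scores_preserve_pairwise_distances(self, rng):
        rows = rng.normal(size=(5, 8))
        res = morpho.pca_relative_warps(self._configs_from_rows(rows))
        centered = rows - rows.mean(0)
        for i in range(5):
            for j in range(5):
                assert np.linalg.norm(res.scores[i] - res.scores[j]) == pytest.approx(
                    np.linalg.norm(centered[i] - centered[j]), abs=1e-9
                )

    def test_duplicated_rows_get_identical_scores(self, rng):
        row = rng.normal(size=8)
        rows = np.vstack([row, row, rng.normal(size=8), rng.normal(size=8)])
        res = morpho.pca_relative_warps(self._configs_from_rows(rows))
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-9)

    def test_needs_two_entities(self, rng):
        with pytest.raises(ValidationError):
            morpho.pca_relative_warps(
                {"g": morpho.LandmarkConfiguration("g", rng.normal(size=(4, 2)), aligned=True)}
            )


class TestBrokenStick:
    def test_single_component(self):
        n, exp = morpho.broken_stick_retention(np.array([2.5]))
        assert n == 1
        np.testing.assert_allclose(exp, [1.0])

    def test_three_component_expectations(self):
        _, exp = morpho.broken_stick_retention(np.array([3.0, 2.0, 1.0]))
        np.testing.assert_allclose(exp, [0.6111, 0.2778, 0.1111], atol=5e-5)

    def test_dominant_pc1_retains_exactly_one(self):
        n, _ = morpho.broken_stick_retention(np.array([95.3, 3.0, 1.7]))
        assert n == 1

    def test_expectations_sum_to_one(self):
        for p in (1, 2, 3, 7, 40):
            _, exp = morpho.broken_stick_retention(np.arange(p, 0, -1.0))
            assert exp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            morpho.broken_stick_retention(np.zeros(3))


class TestTraitDistances:
    def test_pc1_absolute_differences(self):
        scores = pd.DataFrame({"PC1": [0.0, 3.0, 5.0]}, index=["a", "b", "c"])
        d = morpho.trait_distance_matrix(scores)
        ids = list(d.ids)
        assert d[ids.index("a"), ids.index("b")] == pytest.approx(3.0)
        assert d[ids.index("b"), ids.index("c")] == pytest.approx(2.0)
        assert d[ids.index("a"), ids.index("c")] == pytest.approx(5.0)

    def test_translation_invariance(self, rng):
        scores = pd.DataFrame({"PC1": rng.normal(size=6)}, index=list("abcdef"))
        shifted = scores + 42.0
        np.testing.assert_allclose(
            morpho.trait_distance_matrix(scores).data,
            morpho.trait_distance_matrix(shifted).data,
            atol=1e-9,
        )

    def test_multi_component_matches_brute_force(self, rng):
        scores = pd.DataFrame(rng.normal(size=(5, 3)), columns=["PC1", "PC2", "PC3"], index=list("abcde"))
        d = morpho.trait_distance_matrix(scores, components=["PC1", "PC2"])
        x = scores[["PC1", "PC2"]].to_numpy()
        for i in range(5):
            for j in range(5):
                assert d.data[i, j] == pytest.approx(np.linalg.norm(x[i] - x[j]), abs=1e-12)

    def test_duplicate_labels_rejected(self):
        scores = pd.DataFrame({"PC1": [0.0, 1.0]}, index=["a", "a"])
        with pytest.raises(ValidationError):
            morpho.trait_distance_matrix(scores)


class TestTPS:
    def test_round_trip(self, tmp_path, rng):
        configs = [
            morpho.LandmarkConfiguration(f"spec{i}", rng.normal(size=(7, 2))) for i in range(3)
        ]
        path = tmp_path / "lm.tps"
        morpho.write_tps(configs, path)
        again = morpho.read_tps(path)
        assert [c.specimen_id for c in again] == [c.specimen_id for c in configs]
        for a, b in zip(configs, again):
            np.testing.assert_allclose(a.coords, b.coords, rtol=1e-9)

    def test_outline_csv_round_trip(self, tmp_path):
        outline = _circle_outline(n=50, start=3)
        path = tmp_path / "o.csv"
        morpho.write_outline_csv(outline, path)
        again = morpho.read_outline_csv(path, start_index=3)
        np.testing.assert_allclose(again.vertices, outline.vertices, rtol=1e-12)
        assert again.start_index == 3
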
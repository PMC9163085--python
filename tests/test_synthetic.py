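"""Synthetic cohort generator: geometry, connectomes, activity, annotations."""

import numpy as np
import pytest

from sfcoupling import (
    gen_activity,
    gen_annotations,
    gen_connectome,
    gen_geometry,
    spatial_partition,
)
from sfcoupling.synthetic import LATERAL_AXIS, _correlation_target


class TestGeometry:
    def test_bilateral_mirroring(self):
        g = gen_geometry(8, seed=1)
        assert (g.hemisphere == "left").sum() == 4
        assert (g.hemisphere == "right").sum() == 4
        mirror = np.ones(3)
        mirror[LATERAL_AXIS] = -1.0
        np.testing.assert_allclose(
            g.sphere_coord[4:], g.sphere_coord[:4] * mirror, atol=1e-12
        )

    def test_unit_norm(self):
        g = gen_geometry(40, seed=2)
        np.testing.assert_allclose(
            np.linalg.norm(g.sphere_coord, axis=1), 1.0, atol=1e-9
        )

    def test_determinism(self):
        a = gen_geometry(8, seed=1)
        b = gen_geometry(8, seed=1)
        np.testing.assert_array_equal(a.centroid, b.centroid)

    @pytest.mark.parametrize("n", [7, 6, 0])
    def test_invalid_node_counts(self, n):
        with pytest.raises(ValueError):
            gen_geometry(n, seed=1)

    def test_distinct_centroids(self):
        g = gen_geometry(30, seed=3)
        from scipy.spatial.distance import pdist

        assert pdist(g.centroid).min() > 0


class TestConnectome:
    def test_contract(self, geometry20):
        sc = gen_connectome(geometry20, density=0.5, length_scale=40.0, seed=1)
        np.testing.assert_array_equal(sc, sc.T)
        assert np.all(np.diag(sc) == 0)
        assert np.all(sc >= 0)
        from scipy.sparse.csgraph import connected_components, csgraph_from_dense

        n_comp, _ = connected_components(csgraph_from_dense(sc, null_value=0.0))
        assert n_comp == 1

    def test_density_within_tolerance(self, geometry20):
        sc = gen_connectome(geometry20, density=0.4, length_scale=40.0, seed=2)
        iu = np.triu_indices(20, k=1)
        achieved = np.count_nonzero(sc[iu]) / len(iu[0])
        assert abs(achieved - 0.4) / 0.4 <= 0.10

    def test_determinism(self, geometry20):
        a = gen_connectome(geometry20, density=0.5, length_scale=40.0, seed=1)
        b = gen_connectome(geometry20, density=0.5, length_scale=40.0, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_too_sparse_error(self, geometry20):
        with pytest.raises(ValueError, match="connected"):
            gen_connectome(geometry20, density=0.05, length_scale=40.0, seed=1)

    def test_distance_dependence(self):
        """Short-range kernel: chosen edges are shorter than average pairs."""
        from scipy.spatial.distance import squareform, pdist

        shorter = 0
        for seed in range(20):
            g = gen_geometry(30, seed=100 + seed)
            sc = gen_connectome(g, density=0.2, length_scale=10.0, seed=seed)
            d = squareform(pdist(g.centroid))
            iu = np.triu_indices(30, k=1)
            edge_d = d[iu][sc[iu] > 0]
            if edge_d.mean() < d[iu].mean():
                shorter += 1
        assert shorter == 20

    def test_module_boost_concentrates_edges(self, geometry20):
        part = spatial_partition(geometry20, 4, seed=0)
        sc = gen_connectome(
            geometry20, density=0.3, length_scale=40.0, seed=3, modules=part,
            module_boost=25.0,
        )
        iu = np.triu_indices(20, k=1)
        same = part[iu[0]] == part[iu[1]]
        frac_within = np.count_nonzero(sc[iu][same]) / np.count_nonzero(sc[iu])
        assert frac_within > same.mean()  # enriched over chance


class TestActivity:
    def test_alpha_zero_constant_fidelity(self, geometry20, sc20):
        _, truth = gen_activity(
            sc20, geometry20, n_time=60, alpha=0.0, baseline=0.7, timescale=30.0, seed=0
        )
        np.testing.assert_allclose(truth.w, 0.7, atol=1e-12)

    def test_w_bounds_and_mean(self, geometry20, sc20):
        _, truth = gen_activity(
            sc20, geometry20, n_time=400, alpha=0.3, baseline=0.5, timescale=100.0, seed=1
        )
        assert truth.w.min() >= 0.0 and truth.w.max() <= 1.0
        np.testing.assert_allclose(truth.w.mean(axis=1), 0.5, atol=0.05)

    def test_full_fidelity_converges_to_target(self, geometry20, sc20):
        act, _ = gen_activity(
            sc20, geometry20, n_time=5000, alpha=0.0, baseline=1.0, timescale=100.0,
            seed=2,
        )
        target = _correlation_target(sc20, None, None, seed=3)
        emp = np.corrcoef(act)
        assert np.abs(emp - target).max() < 0.1

    def test_zero_fidelity_uncorrelated(self, geometry20, sc20):
        act, _ = gen_activity(
            sc20, geometry20, n_time=5000, alpha=0.0, baseline=0.0, timescale=100.0,
            seed=3,
        )
        emp = np.corrcoef(act)
        off = emp[np.triu_indices(20, k=1)]
        assert np.abs(off).max() < 0.1

    def test_covariance_targeting_monotone(self, geometry20, sc20):
        """Frobenius error to the target decreases with series length."""
        target = _correlation_target(sc20, None, None, seed=0)
        errs = []
        for n_time in (500, 2000, 8000):
            per_seed = []
            for seed in range(3):
                act, _ = gen_activity(
                    sc20, geometry20, n_time=n_time, alpha=0.0, baseline=1.0,
                    timescale=100.0, seed=seed,
                )
                per_seed.append(np.linalg.norm(np.corrcoef(act) - target))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]

    def test_determinism(self, geometry20, sc20):
        a, _ = gen_activity(sc20, geometry20, 100, 0.2, 0.5, 50.0, seed=9)
        b, _ = gen_activity(sc20, geometry20, 100, 0.2, 0.5, 50.0, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_time": 10},
            {"alpha": 1.5},
            {"alpha": 0.6, "baseline": 0.5},
            {"timescale": -1.0},
        ],
    )
    def test_invalid_arguments(self, geometry20, sc20, kwargs):
        args = {"n_time": 100, "alpha": 0.0, "baseline": 0.5, "timescale": 50.0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            gen_activity(sc20, geometry20, seed=0, **args)

    def test_fidelity_map_degrades_static_structure(self, geometry20, sc20):
        """Low-fidelity nodes' profiles decouple from the structural target."""
        q = np.ones(20)
        q[:10] = 0.1
        groups = np.arange(20) // 5
        target = _correlation_target(sc20, q, groups, seed=5)
        pure = _correlation_target(sc20, None, None, seed=5)
        low = np.abs(target[:10, 10:] - pure[:10, 10:]).mean()
        high = np.abs(target[10:, 10:] - pure[10:, 10:]).mean()
        assert low > high


class TestAnnotations:
    def test_all_nodes_labeled(self, geometry20):
        ann = gen_annotations(geometry20, n_networks=2, seed=1)
        assert len(ann.network) == 20
        assert set(np.unique(ann.network)) == {"net1", "net2"}
        assert len(np.unique(ann.cell_class)) >= 2

    def test_determinism(self, geometry20):
        a = gen_annotations(geometry20, n_networks=3, seed=2)
        b = gen_annotations(geometry20, n_networks=3, seed=2)
        np.testing.assert_array_equal(a.network, b.network)
        np.testing.assert_array_equal(a.gradient, b.gradient)

    def test_gradient_spans_range(self, geometry20):
        ann = gen_annotations(geometry20, n_networks=2, seed=3)
        assert ann.gradient.max() - ann.gradient.min() > 0
        assert ann.gradient.min() >= 0.0 and ann.gradient.max() <= 1.0

    def test_too_many_networks_error(self, geometry20):
        with pytest.raises(ValueError):
            gen_annotations(geometry20, n_networks=21, seed=1)

    def test_network_contiguity(self, geometry20):
        """Nearest-seed partitions: each network is spatially compact."""
        ann = gen_annotations(geometry20, n_networks=3, seed=4)
        pts = geometry20.centroid
        for label in np.unique(ann.network):
            members = pts[ann.network == label]
            spread = np.linalg.norm(members - members.mean(axis=0), axis=1).mean()
            global_spread = np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean()
            assert spread < global_spread
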
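"""The synthetic TMA generator: determinism, spatial models, closed-loop recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mxifhet import classify, preprocess
from mxifhet.spatial import neighborhood_composition
from mxifhet.stats import compare_paired_cores
from mxifhet.synthetic import (
    CLASS_TEMPLATES,
    CoreSpec,
    ImmuneSpec,
    InfeasibleIntensityModel,
    IntensityModel,
    ThomasClusterModel,
    default_tma_specs,
    generate_core,
    generate_tma,
    null_pair_specs,
    sample_class_vector,
    shift_fractions,
)


def run_classification(bundle):
    """preprocess + classify closed loop on one bundle."""
    cells, _ = preprocess.normalize_markers(bundle.cells)
    cells = classify.call_positivity(cells)
    meta = bundle.metadata
    cancer = preprocess.select_cancer_population(cells, meta, bundle.regions)
    return classify.assign_eph(cancer)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        specs = default_tma_specs(seed=5, n_cells=150)[:4]
        b1 = generate_tma(specs, seed=11)
        b2 = generate_tma(specs, seed=11)
        assert b1.cells.to_csv(index=False) == b2.cells.to_csv(index=False)
        assert b1.metadata.to_csv(index=False) == b2.metadata.to_csv(index=False)
        assert b1.manifest == b2.manifest

    def test_different_seed_differs(self):
        specs = default_tma_specs(seed=5, n_cells=150)[:2]
        b1 = generate_tma(specs, seed=11)
        b2 = generate_tma(specs, seed=12)
        assert b1.cells.to_csv(index=False) != b2.cells.to_csv(index=False)


class TestGeometryAndComposition:
    def test_all_centroids_inside_disc(self):
        spec = CoreSpec("s", "k", "k", "TNBC", n_cells=2000,
                        class_fractions={1: 0.5, 2: 0.5},
                        spatial_model=ThomasClusterModel(), cluster_by_class=True)
        b = generate_core(spec, seed=3)
        R = spec.radius_px
        d = np.hypot(b.cells["centroid_x"] - R, b.cells["centroid_y"] - R)
        assert (d <= R + 1e-9).all()

    def test_uniform_disc_is_uniform(self):
        # r^2 of a uniform point on a disc is uniform on (0, R^2); angle uniform
        spec = CoreSpec("s", "k", "k", "LumA", n_cells=10_000, other_frac=0.0,
                        immune=ImmuneSpec(0.0, 0.0), class_fractions={13: 0.5, 1: 0.5})
        b = generate_core(spec, seed=9)
        R = spec.radius_px
        x = b.cells["centroid_x"].to_numpy() - R
        y = b.cells["centroid_y"].to_numpy() - R
        p_r = sps.kstest((x**2 + y**2) / R**2, "uniform").pvalue
        p_t = sps.kstest((np.arctan2(y, x) + np.pi) / (2 * np.pi), "uniform").pvalue
        assert p_r > 1e-3 and p_t > 1e-3

    def test_realized_fractions_converge(self):
        fr = {1: 0.25, 2: 0.25, 9: 0.3, 13: 0.2}
        spec = CoreSpec("s", "k", "k", "LumB", n_cells=10_000, other_frac=0.0,
                        immune=ImmuneSpec(0.0, 0.0), class_fractions=fr)
        b = generate_core(spec, seed=1)
        n = b.truth["n_cancer"]
        for cls, p in fr.items():
            realized = b.truth["class_counts_realized"][str(cls)] / n
            assert abs(realized - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_manifest_counts_equal_realized_labels(self):
        b = generate_core(CoreSpec("s", "k", "k", "LumA", n_cells=400,
                                   class_fractions={13: 0.7, 1: 0.3}), seed=2)
        labels = np.array(b.truth["eph_ki67_class"])
        pops = np.array(b.truth["population"])
        for cls, cnt in b.truth["class_counts_realized"].items():
            assert (labels[pops == "cancer"] == int(cls)).sum() == cnt

    def test_bundle_of_three_cores(self):
        specs = default_tma_specs(seed=1, n_cells=120)[:3]
        b = generate_tma(specs, seed=4)
        assert len(b.metadata) == 3
        assert set(b.cells["core_id"]) == {s.core_id for s in specs}
        for s in specs:
            assert (b.cells["core_id"] == s.core_id).sum() == s.n_cells


class TestClosedLoop:
    def test_pure_class_core_recovered_exactly(self):
        spec = CoreSpec("s", "k", "k", "LumA", n_cells=100, class_fractions={1: 1.0})
        b = generate_core(spec, seed=6)
        with pytest.warns(UserWarning):  # ER/PR/HER2/Ki67 all-negative -> degenerate
            cancer = run_classification(b)
        assert len(cancer) > 0
        assert (cancer["eph_ki67_class"] == 1).all()

    def test_mixed_core_recovers_truth_labels(self, rng):
        spec = CoreSpec("s", "k", "k", "LumB_HER2pos", n_cells=1500,
                        class_fractions=CLASS_TEMPLATES["LumB_HER2pos"])
        b = generate_core(spec, seed=8)
        cancer = run_classification(b)
        truth = dict(zip(b.truth["cell_id"], b.truth["eph_ki67_class"]))
        mismatches = sum(
            truth[cid] != cls for cid, cls in zip(cancer["cell_id"], cancer["eph_ki67_class"])
        )
        assert mismatches == 0

    def test_null_pairs_rarely_significant(self):
        # identical-fraction paired cores through the full loop
        n_sig = 0
        n_rep = 25
        for rep in range(n_rep):
            specs = null_pair_specs("LumB", CLASS_TEMPLATES["LumB"], n_pairs=1, n_cells=500,
                                    id_prefix=f"n{rep}")
            b = generate_tma(specs, seed=1000 + rep)
            cells, _ = preprocess.normalize_markers(b.cells)
            cells = classify.call_positivity(cells)
            cancer = classify.assign_eph(
                preprocess.select_cancer_population(cells, b.metadata, b.regions)
            )
            groups = dict(list(cancer.groupby("core_id")))
            a, bb = [g["eph_ki67_class"].to_numpy() for g in groups.values()]
            res = compare_paired_cores(a, bb, n_perm=2000, seed=rep)
            n_sig += res.significant
        assert n_sig <= 2  # expect ~0.25 under a well-calibrated alpha=0.01


class TestSpatialModels:
    def test_class_pure_clusters_enrich_own_class(self):
        fr = {1: 0.5, 9: 0.5}
        spec = CoreSpec("s", "k", "k", "LumB", n_cells=2000, class_fractions=fr,
                        spatial_model=ThomasClusterModel(cluster_sd_px=60.0, offspring_mean=50.0),
                        cluster_by_class=True, other_frac=0.0, immune=ImmuneSpec(0.0, 0.0))
        b = generate_core(spec, seed=12)
        cancer = run_classification(b)
        prof = neighborhood_composition(cancer, class_scheme="EPH8", radius_px=100.0)
        for group in (1, 5):  # classes 1 and 9 are groups 1 and 5
            sub = prof[(prof["central_class"] == group) & (prof["n_neighbors"] > 0)]
            within = (sub[f"nbr_{group}"] / sub["n_neighbors"]).mean()
            global_frac = (cancer["eph_group"] == group).mean()
            assert within > global_frac + 0.1

    def test_aggregated_immune_pattern_clusters(self):
        spec_agg = CoreSpec("s", "k", "k", "HER2", n_cells=2000,
                            class_fractions={1: 0.5, 3: 0.5},
                            immune=ImmuneSpec(0.05, 0.05, "aggregated"))
        spec_sc = CoreSpec("s2", "k2", "k2", "HER2", n_cells=2000,
                           class_fractions={1: 0.5, 3: 0.5},
                           immune=ImmuneSpec(0.05, 0.05, "scattered"))
        dists = {}
        for name, sp in [("agg", spec_agg), ("sc", spec_sc)]:
            b = generate_core(sp, seed=21)
            pops = np.array(b.truth["population"])
            xy = b.cells[["centroid_x", "centroid_y"]].to_numpy()
            cd20 = xy[pops == "CD20"]
            # mean nearest-neighbor distance among CD20 cells
            from scipy.spatial import cKDTree

            d, _ = cKDTree(cd20).query(cd20, k=2)
            dists[name] = d[:, 1].mean()
        assert dists["agg"] < 0.5 * dists["sc"]


class TestIntensityModel:
    def test_infeasible_model_raises(self):
        with pytest.raises(InfeasibleIntensityModel):
            IntensityModel(threshold=1.0, guard=-0.5).validate()

    def test_no_room_above_threshold(self):
        with pytest.raises(InfeasibleIntensityModel):
            IntensityModel(threshold=15.0).validate()

    def test_guard_band_separates_classes(self, rng):
        m = IntensityModel(threshold=5.0)
        pos = np.array([True] * 500 + [False] * 500)
        v = m.draw(pos, rng)
        assert (v[pos] > 5.0).all()
        assert (v[~pos] < 5.0).all()

    def test_leak_rate_flips_calls(self, rng):
        m = IntensityModel(threshold=5.0, leak_rate=0.2)
        pos = np.zeros(4000, dtype=bool)
        v = m.draw(pos, rng)
        leaked = (v > 5.0).mean()
        assert leaked == pytest.approx(0.2, abs=0.03)


class TestHelpers:
    def test_sample_class_vector_distribution(self, rng):
        vec = sample_class_vector({1: 0.5, 9: 0.5}, 4000, rng)
        assert set(vec) == {1, 9}
        assert abs((vec == 1).mean() - 0.5) < 0.05

    def test_shift_fractions_moves_absolute_mass(self):
        fr = shift_fractions({1: 0.6, 9: 0.4}, 1, 9, 0.3)
        assert fr[1] == pytest.approx(0.3) and fr[9] == pytest.approx(0.7)
        capped = shift_fractions({1: 0.1, 9: 0.9}, 1, 9, 0.3)
        assert capped[1] == pytest.approx(0.0)
        assert sum(capped.values()) == pytest.approx(1.0)
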
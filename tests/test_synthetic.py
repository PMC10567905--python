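"""Synthetic abutment/crown generator: geometry and parameter recovery."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from crownfit.errors import SpecError
from crownfit.internal_fit import gap_distances, poisson_disk_sample
from crownfit.margin import extract_above_margin
from crownfit.marginal_fit import hausdorff_margin
from crownfit.meshkit import vertex_adjacency_graph
from crownfit.synthetic import (
    AbutmentSpec,
    CohortSpec,
    CrownSpec,
    generate_cohorts,
    make_abutment,
    make_cohorts,
    make_crown,
)


def roi_mean_gap(abutment, crown, seed, radius=0.15):
    """Mean gap over the intaglio ROI above the margin seal zone (μm)."""
    roi, _ = extract_above_margin(crown.intaglio, crown.margin, 0.6)
    samples = poisson_disk_sample(roi, radius, seed=seed)
    return gap_distances(roi, abutment.mesh, samples).mean


class TestAbutmentGeometry:
    def test_closed_two_manifold(self, abutment):
        tm = abutment.mesh.to_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent
        g = vertex_adjacency_graph(abutment.mesh)
        v, e, f = abutment.mesh.n_vertices, g.number_of_edges(), abutment.mesh.n_faces
        assert v - e + f == 2  # Euler characteristic of a sphere
        assert e == 3 * f // 2

    def test_margin_circumference(self, abutment):
        expected = 2 * np.pi * abutment.spec.base_radius
        assert abutment.margin.arc_length == pytest.approx(expected, rel=0.01)

    def test_cylinder_variant_vertical_walls(self):
        # no wall taper when the top radius equals base minus chamfer width
        spec = AbutmentSpec(base_radius=4.5, top_radius=3.5, chamfer_width=1.0,
                            mesh_resolution=0.25)
        ab = make_abutment(spec)
        # wall faces proper: axial label below the occlusal-edge fillet
        centroids = ab.mesh.triangles().mean(axis=1)
        wall = (ab.face_labels == "axial") & (
            centroids[:, 2] < spec.height - spec.occlusal_fillet - 1e-9)
        normals = ab.mesh.face_normals()[wall]
        assert wall.sum() > 100
        assert np.abs(normals[:, 2]).max() < 1e-6

    def test_resolution_controls_edge_length(self):
        def mean_edge(res):
            ab = make_abutment(AbutmentSpec(mesh_resolution=res))
            g = vertex_adjacency_graph(ab.mesh)
            return np.mean([w for _, _, w in g.edges.data("weight")])

        e1, e2 = mean_edge(0.3), mean_edge(0.15)
        assert e2 == pytest.approx(e1 / 2, rel=0.2)

    def test_coarse_resolution_rejected(self):
        with pytest.raises(SpecError):
            make_abutment(AbutmentSpec(chamfer_width=0.4, mesh_resolution=0.3))


class TestCrownConstruction:
    def test_nominal_spacer_recovered(self, abutment):
        crown = make_crown(abutment, CrownSpec(spacer_um=40))
        assert roi_mean_gap(abutment, crown, seed=1) == pytest.approx(40.0, rel=0.02)
        report = hausdorff_margin(abutment.margin, crown.margin)
        assert report.hausdorff < 5.0

    @pytest.mark.parametrize("spacer", [20.0, 80.0])
    def test_spacer_grid_recovery(self, abutment, spacer):
        crown = make_crown(abutment, CrownSpec(spacer_um=spacer))
        assert roi_mean_gap(abutment, crown, seed=2) == pytest.approx(
            spacer, rel=0.02)

    @pytest.mark.parametrize("extension", [0.1, 0.2, 0.4])
    def test_margin_extension_recovery(self, abutment, extension):
        crown = make_crown(abutment, CrownSpec(margin_extension_error=extension))
        report = hausdorff_margin(abutment.margin, crown.margin)
        assert report.hausdorff == pytest.approx(extension * 1000, rel=0.02)

    def test_doming_localized_and_calibrated(self, abutment):
        crown = make_crown(abutment, CrownSpec(spacer_um=40,
                                               occlusal_doming_um=150))
        samples = poisson_disk_sample(crown.intaglio, 0.15, seed=3)
        field = gap_distances(crown.intaglio, abutment.mesh, samples)
        labels = crown.truth.region_labels[samples.face_indices]
        occ = field.distances[labels == "occlusal"].mean()
        axial = field.distances[labels == "axial"].mean()
        assert occ - axial == pytest.approx(150.0, rel=0.05)

    def test_doming_monotone_in_mean_gap(self, abutment):
        means = [
            roi_mean_gap(abutment, make_crown(abutment, CrownSpec(
                spacer_um=40, occlusal_doming_um=doming)), seed=4)
            for doming in (0.0, 60.0, 150.0)
        ]
        assert means[0] < means[1] < means[2]

    def test_noise_free_truth_capture(self, abutment):
        noisy = make_crown(abutment, CrownSpec(spacer_um=40, noise_sd_um=15, seed=9))
        clean = make_crown(abutment, CrownSpec(spacer_um=40))
        # truth margin curves are identical: noise never reaches the record
        np.testing.assert_allclose(noisy.truth.true_margin_crown.points,
                                   clean.truth.true_margin_crown.points)
        assert noisy.intaglio.vertices.std() != clean.intaglio.vertices.std()

    def test_collapsing_shrinkage_rejected(self, abutment):
        with pytest.raises(SpecError):
            make_crown(abutment, CrownSpec(spacer_um=10, radial_shrinkage=0.04))

    def test_nominal_gap_oracle(self, abutment):
        crown = make_crown(abutment, CrownSpec(spacer_um=40,
                                               occlusal_doming_um=100))
        truth = crown.truth
        # axial wall far above the blend: pure spacer
        assert truth.nominal_gap_um(2.5, abutment.spec.top_radius) == pytest.approx(40.0)
        # margin: no spacer contribution
        assert truth.nominal_gap_um(0.0, abutment.spec.base_radius) == pytest.approx(0.0)
        # occlusal table centre: spacer plus full doming
        assert truth.nominal_gap_um(5.0, 0.0) == pytest.approx(140.0)


class TestCohorts:
    def test_identical_specs_agree(self, abutment):
        cohorts = [CohortSpec(label="a", seating_rotation_sd_deg=0.0,
                              seating_translation_sd_mm=0.0),
                   CohortSpec(label="b", seating_rotation_sd_deg=0.0,
                              seating_translation_sd_mm=0.0)]
        groups = generate_cohorts(abutment, cohorts, n_per_group=2, master_seed=1)
        means = [roi_mean_gap(abutment, crown, seed=5)
                 for crowns in groups.values() for crown in crowns]
        assert max(means) - min(means) < 3.0

    def test_configured_effect_detected(self, abutment):
        """Cohorts with different doming levels separate in the configured
        direction and the pooled t test rejects."""
        from crownfit.stats import student_t_from_raw
        cohorts = [
            CohortSpec(label="conventional", occlusal_doming_um=(180.0, 25.0),
                       seating_rotation_sd_deg=0.0, seating_translation_sd_mm=0.0),
            CohortSpec(label="high_speed", occlusal_doming_um=(120.0, 15.0),
                       seating_rotation_sd_deg=0.0, seating_translation_sd_mm=0.0),
        ]
        groups = generate_cohorts(abutment, cohorts, n_per_group=8, master_seed=2)
        means = {
            label: [roi_mean_gap(abutment, crown, seed=6, radius=0.2)
                    for crown in crowns]
            for label, crowns in groups.items()
        }
        comparison = student_t_from_raw(means["conventional"], means["high_speed"])
        assert np.mean(means["conventional"]) > np.mean(means["high_speed"])
        assert comparison.t < 0  # convention: group2 minus group1
        assert comparison.significant

    def test_file_tree_reproducible(self, tmp_path):
        cohorts = [CohortSpec(label="a", occlusal_doming_um=(100.0, 20.0),
                              noise_sd_um=5.0)]
        spec = AbutmentSpec(mesh_resolution=0.3)
        for sub in ("one", "two"):
            make_cohorts(tmp_path / sub, cohorts, n_per_group=2, master_seed=9,
                         abutment_spec=spec)
        for name in sorted(p.name for p in (tmp_path / "one").iterdir()):
            h1 = hashlib.sha256((tmp_path / "one" / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((tmp_path / "two" / name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_truth_files_match_specs(self, tmp_path):
        import json
        cohorts = [CohortSpec(label="g", spacer_um=(50.0, 5.0))]
        make_cohorts(tmp_path, cohorts, n_per_group=3, master_seed=4,
                     abutment_spec=AbutmentSpec(mesh_resolution=0.3))
        spacers = []
        for path in sorted(Path(tmp_path).glob("*.truth.json")):
            spacers.append(json.loads(path.read_text())["spacer_um"])
        assert len(spacers) == 3
        assert all(35.0 <= s <= 65.0 for s in spacers)  # 3 SD truncation
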
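"""Enhancement chain, length arithmetic, longest-path rule, and tracing
recovery on scenes of known geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from neuroquant import synthetic as syn
from neuroquant.micrograph import Micrograph, ScaleCalibration
from neuroquant import morphometry as morph


def brute_polyline_length(vertices):
    return sum(((r1 - r0) ** 2 + (c1 - c0) ** 2) ** 0.5
               for (r0, c0), (r1, c1) in zip(vertices[:-1], vertices[1:]))


def enumerate_root_leaf_lengths(tree):
    """Exhaustive DFS over every root-to-leaf path, summing edge weights."""
    g, root = tree.graph, tree.soma_anchor
    out = []

    def dfs(node, parent, acc):
        nbrs = [n for n in g[node] if n != parent]
        if not nbrs:
            out.append(acc)
        for n in nbrs:
            dfs(n, node, acc + g[node][n]["weight"])

    dfs(root, None, 0.0)
    return out


class TestPolylineLength:
    def test_single_vertex_is_zero(self):
        assert morph.polyline_length_px(morph.Polyline(((0.0, 0.0),))) == 0.0

    def test_three_four_five(self):
        assert morph.polyline_length_px(morph.Polyline(((0, 0), (3, 4)))) == pytest.approx(5.0)

    def test_matches_segment_oracle(self, rng):
        verts = rng.uniform(0, 100, size=(10, 2))
        p = morph.Polyline.from_array(verts)
        assert morph.polyline_length_px(p) == pytest.approx(
            brute_polyline_length(verts), rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1),
           st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0, 2 * np.pi))
    def test_invariant_under_rigid_motion(self, seed, dr, dc, angle):
        verts = np.random.default_rng(seed).uniform(0, 100, size=(6, 2))
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = verts @ rot.T + [dr, dc]
        l0 = morph.polyline_length_px(morph.Polyline.from_array(verts))
        l1 = morph.polyline_length_px(morph.Polyline.from_array(moved))
        assert l1 == pytest.approx(l0, rel=1e-9)

    def test_repeated_vertices_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            morph.Polyline(((0.0, 0.0), (0.0, 0.0)))


class TestLongestPath:
    def test_single_edge(self):
        t = morph.NeuriteTree((0, 0), [((0, 0), (0, 12.5))])
        assert morph.longest_path_length_px(t) == pytest.approx(12.5)

    def test_stem_and_two_arms_takes_longer_arm(self):
        t = morph.NeuriteTree((0, 0), [
            ((0, 0), (0, 20)), ((0, 20), (30, 20)), ((0, 20), (-50, 20))])
        assert morph.longest_path_length_px(t) == pytest.approx(70.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [(0.0, 0.0)]
        edges = []
        for _ in range(rng.integers(3, 12)):
            parent = nodes[rng.integers(len(nodes))]
            child = tuple(np.asarray(parent) + rng.uniform(-10, 10, 2))
            if child in nodes:
                continue
            nodes.append(child)
            edges.append((parent, child))
        t = morph.NeuriteTree((0.0, 0.0), edges)
        expected = max(enumerate_root_leaf_lengths(t))
        assert morph.longest_path_length_px(t) == pytest.approx(expected, rel=1e-12)
        # the rule never under-reports any single root-to-leaf path
        assert all(morph.longest_path_length_px(t) >= l - 1e-12
                   for l in enumerate_root_leaf_lengths(t))

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            morph.NeuriteTree((0, 0), [((0, 0), (0, 1)), ((0, 1), (1, 1)), ((1, 1), (0, 0))])


class TestCalibration:
    def test_ratio_definition(self):
        cal = ScaleCalibration.from_scale_bar(bar_length_um=100, bar_length_px=250)
        assert cal.um_per_px == pytest.approx(0.4)
        assert morph.calibrate_length(10, cal) == pytest.approx(4.0)
        assert morph.calibrate_length(0, cal) == 0.0
        assert morph.calibrate_length(200, ScaleCalibration(0.5)) == pytest.approx(100.0)

    def test_missing_calibration_fails(self):
        with pytest.raises(ValueError, match="calibration"):
            morph.calibrate_length(10, None)


class TestEnhance:
    def test_constant_image_gives_empty_map(self):
        img = Micrograph(np.full((32, 32), 500, dtype=np.uint16))
        edges = morph.enhance_neurites(img)
        assert edges.shape == img.shape
        assert not edges.any()

    def test_bright_line_pixels_lie_near_edges(self):
        pix = np.full((64, 64), 1000.0)
        line = np.zeros((64, 64), dtype=bool)
        line[32, 8:56] = True
        pix[line] = 30000.0
        img = Micrograph(pix.astype(np.uint16))
        edges = morph.enhance_neurites(img)
        # every true line pixel within 2 px of a detected edge pixel
        dist = ndimage.distance_transform_edt(~edges)
        assert dist[line].max() <= 2.0

    def test_scene_edges_overlap_neurite_mask(self):
        spec = syn.NeuronSceneSpec(n_cells=3)
        img, truth = syn.generate_neuron_scene(spec, seed=6)
        edges = morph.enhance_neurites(img)
        mask = syn.neurite_mask_from_truth(truth, img.shape)
        soma = syn.soma_mask_from_truth(truth, img.shape)
        dilated = ndimage.binary_dilation(edges, structure=np.ones((5, 5), bool))
        mask_only = mask & ~soma
        inter = (dilated & mask_only).sum()
        union_iou = inter / mask_only.sum()  # recall of the true neurite area
        assert union_iou >= 0.5

    def test_binarization_idempotent_and_shape_stable(self, random_micrograph):
        edges = morph.enhance_neurites(random_micrograph)
        assert edges.dtype == bool and edges.shape == random_micrograph.shape

    def test_non_finite_pixels_rejected(self):
        bad = np.ones((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Micrograph(bad)


class TestOverlay:
    def test_empty_map_reproduces_grayscale(self, random_micrograph):
        rgb = morph.overlay_edges(random_micrograph, np.zeros((64, 64), bool))
        gray = (random_micrograph.as_float() / 65535 * 255).round()
        for ch in range(3):
            np.testing.assert_array_equal(rgb[..., ch], gray.astype(np.uint8))

    def test_full_map_paints_everything_blue(self, random_micrograph):
        rgb = morph.overlay_edges(random_micrograph, np.ones((64, 64), bool))
        assert (rgb == np.array([0, 0, 255], dtype=np.uint8)).all()

    def test_exactly_edge_pixels_differ(self, random_micrograph, rng):
        edges = rng.random((64, 64)) < 0.2
        rgb = morph.overlay_edges(random_micrograph, edges)
        plain = morph.overlay_edges(random_micrograph, np.zeros((64, 64), bool))
        differs = (rgb != plain).any(axis=-1)
        np.testing.assert_array_equal(differs, edges)

    def test_shape_mismatch_rejected(self, random_micrograph):
        with pytest.raises(ValueError, match="shape"):
            morph.overlay_edges(random_micrograph, np.zeros((3, 3), bool))


def _scene_with_single_neurite(vertices, soma_center, soma_radius=8.0, width=3.0):
    """Render one soma plus hand-placed polyline(s) exactly as the generator does."""
    canvas = np.zeros((256, 256))
    from skimage.draw import disk as draw_disk
    rr, cc = draw_disk(soma_center, soma_radius, shape=canvas.shape)
    canvas[rr, cc] = 1.0
    for poly in vertices:
        syn._rasterize_polyline(canvas, np.asarray(poly, dtype=float))
    radius = int(round((width - 1) / 2))
    if radius:
        from skimage.morphology import disk as disk_fp
        canvas = ndimage.grey_dilation(canvas, footprint=disk_fp(radius))
    img = 2000 + 38000 * canvas
    micro = Micrograph(np.clip(np.rint(img), 0, 65535).astype(np.uint16))
    soma = np.zeros(canvas.shape, bool)
    soma[rr, cc] = True
    return micro, soma


class TestTrace:
    def test_blank_edge_map_yields_nothing(self):
        soma = np.zeros((64, 64), bool)
        soma[30:34, 30:34] = True
        assert morph.trace_neurites(np.zeros((64, 64), bool), soma) == []

    def test_missing_soma_is_an_error(self):
        with pytest.raises(ValueError, match="soma"):
            morph.trace_neurites(np.ones((32, 32), bool), np.zeros((32, 32), bool))

    def test_unbranched_recovery_within_five_percent(self):
        start = np.array([128.0, 136.0])
        poly = [start, start + [20, 40], start + [10, 80]]
        true_len = brute_polyline_length([tuple(p) for p in poly])
        img, soma = _scene_with_single_neurite([poly], (128, 128))
        edges = morph.enhance_neurites(img)
        trees = morph.trace_neurites(edges, soma, intensity=img.as_float())
        assert len(trees) == 1
        got = morph.longest_path_length_px(trees[0])
        assert got == pytest.approx(true_len, rel=0.05)

    def test_y_branch_follows_longest_arm(self):
        # 20 px stem, arms 30 px and 50 px: the longest path is 70 px
        start = np.array([128.0, 136.0])
        fork = start + [0, 20]
        arm_a = fork + [-30 * np.sin(0.45), 30 * np.cos(0.45)]
        arm_b = fork + [50 * np.sin(0.45), 50 * np.cos(0.45)]
        img, soma = _scene_with_single_neurite(
            [[start, fork, arm_a], [start, fork, arm_b]], (128, 128))
        edges = morph.enhance_neurites(img)
        trees = morph.trace_neurites(edges, soma, intensity=img.as_float())
        assert len(trees) == 1
        got = morph.longest_path_length_px(trees[0])
        assert got == pytest.approx(70.0, rel=0.05)
        # and it exceeds every enumerated root-to-leaf alternative
        assert got == pytest.approx(max(enumerate_root_leaf_lengths(trees[0])), rel=1e-12)


class TestMeasurePicture:
    def test_single_polyline(self):
        pm = morph.measure_picture([morph.Polyline(((0, 0), (3, 4)))],
                                   ScaleCalibration(1.0), picture_id="p1")
        assert pm.lengths_um == [pytest.approx(5.0)]
        assert pm.n == 1

    def test_mixed_inputs_count(self):
        items = [morph.Polyline(((0, 0), (0, 10))),
                 morph.NeuriteTree((0, 0), [((0, 0), (5, 0))])]
        pm = morph.measure_picture(items, ScaleCalibration(2.0))
        assert pm.n == 2
        assert sorted(pm.lengths_um) == [pytest.approx(10.0), pytest.approx(20.0)]

    def test_annotation_mode_reproduces_generator_truth_exactly(self):
        spec = syn.NeuronSceneSpec(n_cells=4, branch_probability=0.4)
        _, truth = syn.generate_neuron_scene(spec, seed=9)
        cal = ScaleCalibration(spec.um_per_px)
        for cell in truth.payload["cells"]:
            for n in cell["neurites"]:
                polys = [morph.Polyline.from_array(p) for p in n["paths"]]
                lengths = [morph.polyline_length_px(p) for p in polys]
                got_um = morph.calibrate_length(max(lengths), cal)
                assert got_um == pytest.approx(n["length_um"], rel=1e-9)

    def test_empty_picture_rejected(self):
        with pytest.raises(ValueError, match="no measurements"):
            morph.measure_picture([], ScaleCalibration(1.0), "p")
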
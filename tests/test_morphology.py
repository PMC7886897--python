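"""Morphology IO, generation and classification."""

import math

import numpy as np
import pytest

from stellate.morphology import (
    GenerationError,
    Morphology,
    MorphometricTargets,
    Segment,
    classify_compartments,
    generate_sc_morphology,
    morphometrics,
    read_swc,
    write_swc,
)


def _two_segment_morph():
    soma = Segment(0, -1, "soma", [[0, -2, 0], [0, 2, 0]], [4.0, 4.0])
    dend = Segment(1, 0, "dendrite", [[0, 2, 0], [0, 12, 0]], [1.0, 0.8])
    return Morphology([soma, dend])


class TestSWC:
    def test_minimal_tree_reads(self, tmp_path):
        path = tmp_path / "min.swc"
        path.write_text(
            "1 1 0 0 0 2.0 -1\n2 1 0 4 0 2.0 1\n3 3 0 14 0 0.5 2\n"
        )
        m = read_swc(path)
        labels = sorted(s.label for s in m.segments)
        assert labels == ["dendrite", "soma"]

    def test_round_trip_preserves_topology_and_metrics(self, tmp_path):
        m = generate_sc_morphology(seed=3)
        path = tmp_path / "cell.swc"
        write_swc(m, path)
        m2 = read_swc(path)
        a, b = morphometrics(m), morphometrics(m2)
        for key in ("total_dendritic_length_um", "ais_length_um", "axon_length_um"):
            assert a[key] == pytest.approx(b[key], rel=1e-6)
        assert a["proximal_segment_count"] == b["proximal_segment_count"]
        assert a["distal_segment_count"] == b["distal_segment_count"]

    @pytest.mark.parametrize(
        "content, message",
        [
            ("1 1 0 0 0 2.0 -1\n2 3 0 1 0\n", "columns"),
            ("1 1 0 0 0 2.0 -1\n2 3 0 1 0 0.5 -1\n", "root"),
            ("1 9 0 0 0 2.0 -1\n", "type"),
        ],
    )
    def test_malformed_swc_rejected(self, tmp_path, content, message):
        path = tmp_path / "bad.swc"
        path.write_text(content)
        with pytest.raises(ValueError, match=message):
            read_swc(path)

    def test_total_length_matches_brute_force(self, tmp_path, rng):
        # random tree of ~80 points written as SWC; oracle = direct
        # summation of inter-point euclidean distances
        lines = ["1 1 0 0 0 2.0 -1"]
        pts = {1: np.zeros(3)}
        expected = 0.0
        for nid in range(2, 81):
            parent = int(rng.integers(1, nid))
            step = rng.normal(0, 3, 3)
            pts[nid] = pts[parent] + step
            typ = 3
            if parent != 1:
                expected += float(np.linalg.norm(step))
            else:
                expected += float(np.linalg.norm(pts[nid] - pts[1]))
            x, y, z = pts[nid]
            lines.append(f"{nid} {typ} {x:.6f} {y:.6f} {z:.6f} 0.5 {parent}")
        path = tmp_path / "tree.swc"
        path.write_text("\n".join(lines) + "\n")
        m = read_swc(path)
        # coordinates quantized to 1e-6 um on write
        assert morphometrics(m)["total_dendritic_length_um"] == pytest.approx(
            expected, rel=1e-7
        )


class TestGenerator:
    def test_targets_met_within_one_sd(self):
        targets = MorphometricTargets()
        m = generate_sc_morphology(targets, seed=1)
        mm = morphometrics(m)
        mean, sd = targets.total_dendritic_length_um
        assert abs(mm["total_dendritic_length_um"] - mean) <= sd
        assert abs(mm["proximal_segment_count"] - 11.0) <= 3.0
        assert abs(mm["distal_segment_count"] - 63.5) <= 14.0

    def test_same_seed_is_deterministic(self):
        a = generate_sc_morphology(seed=7)
        b = generate_sc_morphology(seed=7)
        assert morphometrics(a) == morphometrics(b)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_allclose(sa.points, sb.points)

    def test_mean_soma_surface_tracks_target(self):
        surfaces = [
            morphometrics(generate_sc_morphology(seed=s))["soma_surface_um2"]
            for s in range(25)
        ]
        assert abs(float(np.mean(surfaces)) - 42.4) <= 9.3

    def test_all_five_classes_present_and_connected(self):
        m = generate_sc_morphology(seed=11)
        cls = set(classify_compartments(m).values())
        assert cls == {
            "soma",
            "proximal_dendrite",
            "distal_dendrite",
            "ais",
            "axon",
        }
        m.validate()  # single connected rooted tree

    def test_unreachable_targets_raise(self):
        bad = MorphometricTargets(dendrite_diameter_cutoff_um=0.05)
        with pytest.raises(GenerationError):
            generate_sc_morphology(bad, seed=0, max_attempts=3)


class TestClassification:
    @pytest.mark.parametrize(
        "diameter, expected",
        [(0.7, "proximal_dendrite"), (0.5, "distal_dendrite")],
    )
    def test_cutoff_splits_dendrites(self, diameter, expected):
        soma = Segment(0, -1, "soma", [[0, 0, 0], [0, 4, 0]], [4.0, 4.0])
        dend = Segment(
            1, 0, "dendrite", [[0, 4, 0], [0, 14, 0]], [diameter, diameter]
        )
        cls = classify_compartments(Morphology([soma, dend]))
        assert cls[1] == expected

    def test_axon_never_dendritic(self):
        soma = Segment(0, -1, "soma", [[0, 0, 0], [0, 4, 0]], [4.0, 4.0])
        axon = Segment(1, 0, "axon", [[0, 4, 0], [0, 40, 0]], [0.3, 0.3])
        assert classify_compartments(Morphology([soma, axon]))[1] == "axon"


class TestMorphometrics:
    def test_cylinder_lateral_surface(self):
        seg = Segment(1, 0, "dendrite", [[0, 0, 0], [10, 0, 0]], [1.0, 1.0])
        assert seg.surface() == pytest.approx(10 * math.pi)

    def test_empty_dendrites_zero_length(self):
        soma = Segment(0, -1, "soma", [[0, 0, 0], [0, 4, 0]], [4.0, 4.0])
        mm = morphometrics(Morphology([soma]))
        assert mm["total_dendritic_length_um"] == 0.0
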
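"""Varicosity detection, size gating, Syt-1 classification and spacing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axovuln.morphometry import segment_neurites, skeletonize
from axovuln.synthetic import generate_straight_field
from axovuln.varicosity import (
    Varicosity,
    classify_syt1,
    density_per_length,
    detect_varicosities,
    nn_distances,
    passes_size_gate,
    summarize,
    syt1_cutoff,
)
from tests.conftest import greedy_match


def _vari(x=0.0, y=0.0, width=0.5, length=1.0, syt1=50.0, gate=True):
    return Varicosity((x, y), width, length, syt1, gate)


def _detect_on_straight(widths, **kwargs):
    field, truth = generate_straight_field(widths, **kwargs)
    graph = skeletonize(segment_neurites(field, None), field.pixel_size_um)
    return detect_varicosities(field, graph), truth


class TestSizeGate:
    @pytest.mark.parametrize(
        "width,length,expected",
        [
            (0.2, 1.0, True),   # lower width boundary inclusive
            (1.0, 1.0, True),   # upper width boundary inclusive
            (0.19, 1.0, False),
            (1.01, 1.0, False),
            (0.5, 0.3, True),   # lower length boundary
            (0.5, 0.29, False),
            (0.5, 5.0, True),   # default upper length boundary
            (0.5, 5.01, False),
        ],
    )
    def test_default_gate_boundaries(self, width, length, expected):
        assert passes_size_gate(width, length) is expected

    @pytest.mark.parametrize(
        "length,expected", [(0.3, True), (0.5, True), (0.51, False), (1.0, False)]
    )
    def test_strict_length_gate(self, length, expected):
        assert passes_size_gate(0.5, length, strict_length_gate=True) is expected

    def test_gate_is_pure_function_of_geometry(self):
        rng = np.random.default_rng(0)
        cands = [
            _vari(width=w, length=l, gate=passes_size_gate(w, l))
            for w, l in zip(rng.uniform(0.1, 2, 50), rng.uniform(0.1, 6, 50))
        ]
        flags = [v.passes_gate for v in cands]
        order = rng.permutation(50)
        assert [cands[i].passes_gate for i in order] == [flags[i] for i in order]


class TestDetection:
    def test_ten_planted_enlargements_recovered(self):
        dets, truth = _detect_on_straight(np.full(10, 0.6), seed=1)
        pairs = greedy_match(
            [v.centroid_um for v in dets],
            [v.centroid_um for v in truth.varicosities],
            1.0,
        )
        assert len(pairs) >= 9

    def test_oversized_enlargement_fails_gate(self):
        # a 1.5 um wide blob is detected but excluded by the width gate
        dets, truth = _detect_on_straight([1.5, 0.6, 1.5], spacing_um=10.0, seed=2)
        pairs = greedy_match(
            [v.centroid_um for v in dets],
            [v.centroid_um for v in truth.varicosities],
            1.0,
        )
        matched = {j: i for i, j in pairs}
        for j, v_true in enumerate(truth.varicosities):
            if v_true.width_um > 1.0 and j in matched:
                assert not dets[matched[j]].passes_gate

    def test_uniform_neurite_yields_nothing(self):
        dets, _ = _detect_on_straight(np.empty(0), seed=3)
        assert dets == []

    def test_empty_skeleton_empty_list(self):
        field, _ = generate_straight_field(np.empty(0), seed=0)
        graph = skeletonize(np.zeros(field.shape, bool), field.pixel_size_um)
        assert detect_varicosities(field, graph) == []


class TestSyt1Cutoff:
    def test_constant_intensities(self):
        cands = [_vari(syt1=10.0, gate=False)] * 8
        cutoff, fallback = syt1_cutoff(cands)
        assert cutoff == pytest.approx(10.0)
        assert not fallback

    def test_uniform_grid_percentile(self):
        cands = [_vari(syt1=float(i), gate=False) for i in range(1, 101)]
        cutoff, _ = syt1_cutoff(cands)
        assert abs(cutoff - 95.0) <= 1.0

    def test_fallback_to_background(self):
        cutoff, fallback = syt1_cutoff(
            [_vari(gate=False)] * 2, background_mean=5.0, background_sd=2.0
        )
        assert cutoff == pytest.approx(9.0)
        assert fallback

    def test_no_candidates_no_background_errors(self):
        with pytest.raises(ValueError):
            syt1_cutoff([])

    def test_cutoff_separates_mixture_components(self):
        # cutoff from the negative component stays below the positive mean
        rng = np.random.default_rng(42)
        neg_mean, pos_mean, sd = 20.0, 120.0, 10.0
        below = 0
        n_sim = 200
        for _ in range(n_sim):
            cands = [
                _vari(syt1=float(rng.normal(neg_mean, sd)), gate=False)
                for _ in range(20)
            ]
            cutoff, _ = syt1_cutoff(cands)
            below += cutoff < pos_mean
        assert below / n_sim >= 0.95

    def test_mean_plus_2sd_method(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(30, 5, 50)
        cands = [_vari(syt1=float(v), gate=False) for v in vals]
        cutoff, _ = syt1_cutoff(cands, method="mean+2sd")
        assert cutoff == pytest.approx(vals.mean() + 2 * vals.std(ddof=1))


class TestClassify:
    def test_all_below_cutoff(self):
        cands = [_vari(syt1=s) for s in (1.0, 2.0, 3.0)]
        assert classify_syt1(cands, 10.0) == 0.0

    def test_half_above(self):
        cands = [_vari(syt1=5.0), _vari(syt1=15.0)]
        assert classify_syt1(cands, 10.0) == pytest.approx(0.5)

    def test_no_passing_candidates_nan(self):
        assert np.isnan(classify_syt1([_vari(gate=False)], 10.0))

    def test_fraction_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        cands = [_vari(syt1=float(s)) for s in rng.uniform(0, 100, 200)]
        fracs = [classify_syt1(cands, c) for c in (10.0, 30.0, 60.0, 90.0)]
        assert fracs == sorted(fracs, reverse=True)

    def test_planted_fraction_recovered(self):
        # pooled straight-neurite fields: planted positive fraction 0.7
        rng = np.random.default_rng(7)
        dets, planted = [], []
        for seed in range(10):
            n_in, n_off = 28, 6
            widths = np.concatenate(
                [rng.uniform(0.3, 0.9, n_in), rng.uniform(1.2, 1.8, n_off)]
            )
            pos = np.concatenate(
                [rng.random(n_in) < 0.7, np.zeros(n_off, bool)]
            )
            order = rng.permutation(n_in + n_off)
            field, truth = generate_straight_field(
                widths[order], syt1_positive=pos[order], spacing_um=6.0,
                seed=300 + seed,
            )
            graph = skeletonize(segment_neurites(field, None), field.pixel_size_um)
            dets += detect_varicosities(field, graph)
            planted += [
                v.is_syt1_positive for v in truth.varicosities
                if 0.2 <= v.width_um <= 1.0
            ]
        assert sum(v.passes_gate for v in dets) >= 250
        cutoff, _ = syt1_cutoff([v for v in dets if not v.passes_gate])
        frac = classify_syt1(dets, cutoff)
        assert abs(frac - np.mean(planted)) < 0.05


class TestSpacing:
    def test_collinear_distances(self):
        cands = [_vari(x=x) for x in (0.0, 3.0, 7.0)]
        np.testing.assert_allclose(sorted(nn_distances(cands)), [3.0, 3.0, 4.0])

    def test_pair_is_symmetric(self):
        cands = [_vari(x=0.0), _vari(x=2.5)]
        np.testing.assert_allclose(nn_distances(cands), [2.5, 2.5])

    def test_single_point_empty(self):
        assert nn_distances([_vari()]).size == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 100))
    def test_matches_bruteforce(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(n, 2))
        cands = [_vari(x=float(x), y=float(y)) for x, y in pts]
        got = nn_distances(cands)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        np.testing.assert_array_equal(got, d.min(axis=1))


class TestDensity:
    def test_per_mm(self):
        cands = [_vari(x=float(i)) for i in range(30)]
        assert density_per_length(cands, 1000.0) == pytest.approx(30.0)

    def test_zero_varicosities(self):
        assert density_per_length([], 500.0) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            density_per_length([_vari()], 0.0)

    def test_summary_consistency(self):
        cands = [_vari(x=float(3 * i), syt1=s) for i, s in enumerate((5, 15, 25))]
        classify_syt1(cands, 10.0)
        m = summarize(cands, 3000.0, "f")
        assert m.n_passing == 3
        assert m.syt1_positive_fraction == pytest.approx(2 / 3)
        assert m.density_per_mm == pytest.approx(1.0)
        assert len(m.nn_distances_um) == 3
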
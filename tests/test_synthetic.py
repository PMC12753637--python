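"""Synthetic IHC generator: construction-time ground truth and determinism."""

from dataclasses import replace

import numpy as np
import pytest

from pdl1tps.quantify import count_cells, compute_tps
from pdl1tps.synthetic import (CohortSpec, PlacementError, SyntheticPatchSpec,
                               generate_case, generate_cohort, generate_patch)


class TestGeneratePatch:
    def test_requested_counts_realised(self):
        spec = SyntheticPatchSpec(n_positive=10, n_negative=40)
        _, mask, tally = generate_patch(spec, 1)
        assert (tally.n_positive, tally.n_negative) == (10, 40)
        assert compute_tps(tally) == pytest.approx(20.0)
        # ground-truth closure: counting the mask reproduces the tally
        assert count_cells(mask) == tally

    def test_empty_spec_gives_blank_mask(self):
        _, mask, tally = generate_patch(SyntheticPatchSpec(), 0)
        assert not mask.any()
        assert tally.total == 0

    def test_bit_identical_for_same_seed(self):
        spec = SyntheticPatchSpec(n_positive=3, n_negative=3, n_distractor=1)
        img1, msk1, _ = generate_patch(spec, 5)
        img2, msk2, _ = generate_patch(spec, 5)
        assert img1.tobytes() == img2.tobytes()
        assert msk1.tobytes() == msk2.tobytes()

    def test_different_seeds_differ(self):
        spec = SyntheticPatchSpec(n_positive=3, n_negative=3)
        img1, _, _ = generate_patch(spec, 5)
        img2, _, _ = generate_patch(spec, 6)
        assert img1.tobytes() != img2.tobytes()

    def test_mask_values_are_labels(self):
        spec = SyntheticPatchSpec(n_positive=5, n_negative=5, n_distractor=3)
        _, mask, _ = generate_patch(spec, 2)
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_distractors_are_background_labelled(self):
        spec = SyntheticPatchSpec(n_positive=0, n_negative=0, n_distractor=5)
        img, mask, tally = generate_patch(spec, 9)
        assert not mask.any()            # distractor pixels carry label 0
        assert tally.total == 0
        # ... but they do stain the image
        assert (np.abs(img.astype(int) - [233, 213, 218]).sum(-1) > 120).any()

    def test_infeasible_packing_raises(self):
        spec = SyntheticPatchSpec(height_px=48, width_px=48, n_positive=50,
                                  cell_radius_range=(5, 9))
        with pytest.raises(PlacementError):
            generate_patch(spec, 0)

    def test_straddle_free_cells_stay_within_tiles(self):
        spec = SyntheticPatchSpec(height_px=128, width_px=128, n_positive=4,
                                  n_negative=4, cell_radius_range=(3, 5),
                                  min_cell_gap_px=10,
                                  forbid_tile_straddle=True, tile_size_px=64)
        _, mask, _ = generate_patch(spec, 4)
        # no foreground pixel column/row pair straddles a tile boundary:
        # each connected cell must fall inside exactly one 64-px tile
        from pdl1tps.quantify import label_cells
        for lab in (1, 2):
            for cell in label_cells(mask, lab):
                ys, xs = np.nonzero(cell)
                assert ys.min() // 64 == ys.max() // 64
                assert xs.min() // 64 == xs.max() // 64

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SyntheticPatchSpec(n_positive=-1)
        with pytest.raises(ValueError):
            SyntheticPatchSpec(cell_radius_range=(5, 3))
        with pytest.raises(ValueError):
            SyntheticPatchSpec(stain_intensity=1.5)


class TestGenerateCase:
    def test_tallies_are_additive(self):
        spec = SyntheticPatchSpec(n_positive=5, n_negative=15)
        case = generate_case(spec, 4, 1)
        assert (case.true_tally.n_positive, case.true_tally.n_negative) == (20, 60)
        assert case.true_tps == pytest.approx(25.0)

    def test_all_negative_case_scores_zero(self):
        spec = SyntheticPatchSpec(n_positive=0, n_negative=10)
        case = generate_case(spec, 1, 2)
        assert case.true_tps == pytest.approx(0.0)

    def test_per_patch_counts_override(self):
        spec = SyntheticPatchSpec()
        case = generate_case(spec, 2, 3, per_patch_counts=[(1, 0), (0, 1)])
        assert case.true_tps == pytest.approx(50.0)

    def test_no_cells_yields_no_score(self):
        case = generate_case(SyntheticPatchSpec(), 2, 0)
        assert case.true_tps is None

    def test_invalid_patch_count(self):
        with pytest.raises(ValueError):
            generate_case(SyntheticPatchSpec(), 0, 1)


@pytest.fixture(scope="module")
def small_cohort_spec():
    template = SyntheticPatchSpec(height_px=64, width_px=64,
                                  cell_radius_range=(3, 5),
                                  min_cell_gap_px=10)
    return CohortSpec(n_cases=10, category_proportions=(0.2, 0.4, 0.4),
                      per_case_patch_count=2, seed=7,
                      patch_template=template, cells_per_patch_range=(3, 4),
                      max_distractors_per_patch=1)


class TestGenerateCohort:
    def test_category_counts_follow_rounding(self, small_cohort_spec):
        cases = generate_cohort(small_cohort_spec)
        cats = [c.category for c in cases]
        assert cats.count("<1%") == 2
        assert cats.count("1-49%") == 4
        assert cats.count(">=50%") == 4

    def test_true_tps_falls_in_assigned_category(self, small_cohort_spec):
        bounds = {"<1%": (0.0, 1.0), "1-49%": (1.0, 50.0),
                  ">=50%": (50.0, 100.0)}
        for case in generate_cohort(small_cohort_spec):
            lo, hi = bounds[case.category]
            assert lo <= case.true_tps < hi or (hi == 100.0 and
                                                case.true_tps == 100.0)

    def test_single_case_low_category(self):
        spec = CohortSpec(n_cases=1, category_proportions=(1.0, 0.0, 0.0),
                          per_case_patch_count=1,
                          patch_template=SyntheticPatchSpec(
                              height_px=64, width_px=64,
                              cell_radius_range=(3, 5), min_cell_gap_px=10),
                          cells_per_patch_range=(3, 4))
        (case,) = generate_cohort(spec)
        assert case.true_tps < 1.0

    def test_fixed_seed_reproducible(self, small_cohort_spec):
        a = generate_cohort(small_cohort_spec)
        b = generate_cohort(small_cohort_spec)
        assert [c.true_tps for c in a] == [c.true_tps for c in b]
        assert all(p1[0].tobytes() == p2[0].tobytes()
                   for c1, c2 in zip(a, b)
                   for p1, p2 in zip(c1.patches, c2.patches))

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_cases=5, category_proportions=(0.5, 0.4, 0.4))


class TestGroundTruthClosure:
    def test_generator_tally_matches_component_count(self):
        # gap wide enough that the radius-4 merge can never fuse two cells
        for seed in range(5):
            spec = SyntheticPatchSpec(n_positive=8, n_negative=12,
                                      n_distractor=2, min_cell_gap_px=12)
            _, mask, tally = generate_patch(spec, seed)
            assert count_cells(mask) == tally
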
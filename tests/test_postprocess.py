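import numpy as np
import pytest

from nucleiquant import PipelineParams, Status, apply_postprocessing
from nucleiquant.postprocess import (
    detect_block,
    eliminate_invisible,
    eliminate_small,
    find_double_counts,
    intersection_percent,
)
from nucleiquant.stack_model import ConsistencyError

from conftest import make_mask


def square(top, left, side, **kw):
    return make_mask(
        [(r, c) for r in range(top, top + side) for c in range(left, left + side)],
        **kw,
    )


class TestIntersectionPercent:
    def test_identical_masks_score_100(self):
        a = square(0, 0, 5)
        b = square(0, 0, 5, label_id=2)
        assert intersection_percent(a, b) == 100.0

    def test_disjoint_masks_score_0(self):
        assert intersection_percent(square(0, 0, 3), square(10, 10, 3, label_id=2)) == 0.0

    def test_contained_mask_scores_100_with_min_denominator(self):
        small = square(2, 2, 5)  # 25 px inside the 100 px mask
        big = square(0, 0, 10, label_id=2)
        assert intersection_percent(small, big) == 100.0
        assert intersection_percent(small, big, denominator="union") == 25.0

    def test_symmetric(self):
        a = square(0, 0, 4)
        b = square(2, 2, 4, label_id=2)
        assert intersection_percent(a, b) == intersection_percent(b, a)


class TestFindDoubleCounts:
    def test_identical_copy_in_adjacent_substacks_eliminates_higher(self):
        a = square(5, 5, 10, substack_index=2)
        b = square(5, 5, 10, label_id=2, substack_index=3)
        pairs = find_double_counts([[], [], [a], [b]], threshold_pct=60)
        assert len(pairs) == 1
        assert pairs[0].eliminated is b  # area tie: higher substack goes
        assert a.status is Status.ACCEPTED and b.status is Status.DOUBLE_COUNTED

    def test_overlap_at_50_percent_with_threshold_60_retains_both(self):
        a = square(0, 0, 4, substack_index=0)  # 16 px
        b = make_mask(
            [(r, c) for r in range(4) for c in range(2, 6)],
            label_id=2,
            substack_index=1,
        )  # overlap 8 px = 50% of the smaller
        pairs = find_double_counts([[a], [b]], threshold_pct=60)
        assert pairs == []
        assert a.status is Status.ACCEPTED and b.status is Status.ACCEPTED

    def test_smaller_mask_is_the_one_eliminated(self):
        small = square(2, 2, 5, substack_index=0)
        big = square(0, 0, 10, label_id=2, substack_index=1)
        (pair,) = find_double_counts([[small], [big]], threshold_pct=60)
        assert pair.eliminated is small and pair.survivor is big
        assert pair.eliminated.area_px <= pair.survivor.area_px

    def test_marked_mask_joins_no_further_comparisons(self):
        # the same footprint in three consecutive substacks: the middle copy
        # is eliminated against the first; the third then has no live partner
        copies = [
            square(5, 5, 8, substack_index=i, label_id=1) for i in range(3)
        ]
        pairs = find_double_counts([[c] for c in copies], threshold_pct=60)
        assert len(pairs) == 1
        assert [c.status for c in copies] == [
            Status.ACCEPTED, Status.DOUBLE_COUNTED, Status.ACCEPTED
        ]

    def test_threshold_100_with_partial_overlap_finds_nothing(self):
        a = square(0, 0, 4, substack_index=0)
        b = make_mask(
            [(r, c) for r in range(4) for c in range(1, 5)],
            label_id=2,
            substack_index=1,
        )
        assert find_double_counts([[a], [b]], threshold_pct=100) == []

    def test_single_substack_compares_nothing(self):
        assert find_double_counts([[square(0, 0, 4)]], threshold_pct=60) == []


class TestEliminationRules:
    def test_small_rule_is_strictly_below_limit(self):
        at_limit = square(0, 0, 10)  # exactly 100 px
        below = make_mask([(0, c) for c in range(99)])
        assert eliminate_small(at_limit, 100) is Status.ACCEPTED
        assert eliminate_small(below, 100) is Status.SMALL

    def test_invisible_rule_strict_majority_and_strict_intensity(self):
        image = np.zeros((4, 10), dtype=np.uint8)
        image[0, 6:] = 200
        mask_60_dark = make_mask([(0, c) for c in range(10)], image=image)
        assert eliminate_invisible(mask_60_dark, image, 16) is Status.INVISIBLE

        image2 = np.zeros((1, 10), dtype=np.uint8)
        image2[0, 5:] = 200  # exactly 50% dark is not a strict majority
        mask_half = make_mask([(0, c) for c in range(10)], image=image2)
        assert eliminate_invisible(mask_half, image2, 16) is Status.ACCEPTED

        image3 = np.full((1, 10), 16, dtype=np.uint8)  # at the limit = visible
        mask_at_limit = make_mask([(0, c) for c in range(10)], image=image3)
        assert eliminate_invisible(mask_at_limit, image3, 16) is Status.ACCEPTED

    def test_eliminated_mask_not_reclassified(self):
        image = np.zeros((1, 50), dtype=np.uint8)
        mask = make_mask([(0, c) for c in range(50)], image=image)
        mask.status = Status.DOUBLE_COUNTED
        assert eliminate_small(mask, 100) is Status.DOUBLE_COUNTED
        assert eliminate_invisible(mask, image, 16) is Status.DOUBLE_COUNTED


class TestDetectBlock:
    def _bright_mask(self, n_px, intensity=200):
        image = np.full((1, n_px), intensity, dtype=np.uint8)
        return make_mask([(0, c) for c in range(n_px)], image=image), image

    def test_big_bright_mask_estimated_by_area_ratio(self):
        mask, image = self._bright_mask(1200)
        assert detect_block(mask, image, 800, 127, 400) is Status.BIG
        assert mask.estimated_count == 3  # 1200 / 400

    def test_round_half_up_of_estimate(self):
        mask, image = self._bright_mask(1000)
        detect_block(mask, image, 800, 127, 400)
        assert mask.estimated_count == 3  # 2.5 rounds half-up

    def test_dark_majority_fails_brightness_condition(self):
        image = np.zeros((1, 1200), dtype=np.uint8)
        image[0, :480] = 200  # only 40% bright
        image[0, 480:] = 100
        mask = make_mask([(0, c) for c in range(1200)], image=image)
        assert detect_block(mask, image, 800, 127, 400) is Status.ACCEPTED
        assert mask.estimated_count == 1

    def test_area_at_limit_is_not_big(self):
        mask, image = self._bright_mask(800)
        assert detect_block(mask, image, 800, 127, 400) is Status.ACCEPTED


class TestApplyPostprocessing:
    def _image(self, shape=(64, 64), fill=200):
        return np.full(shape, fill, dtype=np.uint8)

    def test_identity_pipeline_when_nothing_matches(self):
        image = self._image()
        masks = [
            [square(2, 2, 12, image=image, label_id=1),
             square(30, 30, 12, label_id=2, image=image)],
            [square(2, 40, 12, image=image, substack_index=1)],
        ]
        result = apply_postprocessing(masks, [image, image], PipelineParams())
        assert result.final_count == result.raw_count == 3
        assert result.removed_count == 0

    def test_precedence_small_before_invisible(self):
        image = np.zeros((16, 16), dtype=np.uint8)  # dark AND small
        mask = square(0, 0, 5, image=image)
        result = apply_postprocessing([[mask]], [image], PipelineParams())
        assert mask.status is Status.SMALL
        assert result.counts_by_status[Status.INVISIBLE] == 0

    def test_bookkeeping_invariants(self):
        image = self._image((64, 64))
        dark = np.zeros((64, 64), dtype=np.uint8)
        masks = [
            [square(0, 0, 12, image=image),  # accepted, 144 px
             square(20, 20, 5, label_id=2, image=image)],  # small
            [square(0, 0, 12, image=dark, substack_index=1)],  # duplicate, dark
        ]
        result = apply_postprocessing(masks, [image, dark], PipelineParams())
        counts = result.counts_by_status
        assert sum(counts.values()) == result.raw_count == 3
        assert result.removed_count == (
            counts[Status.DOUBLE_COUNTED] + counts[Status.SMALL] + counts[Status.INVISIBLE]
        )
        assert result.final_count == counts[Status.ACCEPTED] + sum(
            m.estimated_count
            for row in result.substack_masks
            for m in row
            if m.status is Status.BIG
        )

    def test_double_count_takes_precedence_over_invisible(self):
        # the duplicate in the dark substack is removed as a double count,
        # not as invisible, because the colocalization pass runs first
        image = self._image((32, 32))
        dark = np.zeros((32, 32), dtype=np.uint8)
        a = square(4, 4, 10, image=image)
        b = square(4, 4, 10, image=dark, substack_index=1)
        result = apply_postprocessing([[a], [b]], [image, dark], PipelineParams())
        assert b.status is Status.DOUBLE_COUNTED
        assert result.final_count == 1

    def test_mismatched_substack_counts_rejected(self):
        image = self._image((16, 16))
        with pytest.raises(ConsistencyError):
            apply_postprocessing([[]], [image, image], PipelineParams())

    def test_idempotent_on_surviving_masks(self):
        image = self._image()
        masks = [
            [square(2, 2, 12, image=image),
             square(40, 40, 11, label_id=2, image=image)],
            [square(20, 20, 12, image=image, substack_index=1)],
        ]
        first = apply_postprocessing(masks, [image, image], PipelineParams())
        survivors = [
            [m for m in row if m.status is Status.ACCEPTED]
            for row in first.substack_masks
        ]
        second = apply_postprocessing(survivors, [image, image], PipelineParams())
        assert second.final_count == first.final_count
        assert second.removed_count == 0
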
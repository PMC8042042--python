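"""Generator and cohort-filter behaviour."""

import numpy as np
import pandas as pd
import pytest

from crstress import synthdata
from crstress.synthdata import (LesionMask, cohort_filter, generate_cohort,
                                generate_study)


class TestGenerateStudy:
    def test_normal_study_has_no_masks(self):
        study = generate_study(1, "normal", 256, 320, 0.8)
        assert all(not m.present for m in study.masks.values())
        assert all(not m.mask.any() for m in study.masks.values())

    def test_seeded_determinism_bit_identical(self):
        a = generate_study(1, "malignant", 256, 320, 0.8)
        b = generate_study(1, "malignant", 256, 320, 0.8)
        for v in synthdata.VIEWS:
            np.testing.assert_array_equal(a.views[v].pixels, b.views[v].pixels)
            np.testing.assert_array_equal(a.masks[v].mask, b.masks[v].mask)

    def test_different_seeds_differ(self):
        a = generate_study(1, "normal", 128, 160, 0.8)
        b = generate_study(2, "normal", 128, 160, 0.8)
        assert not np.array_equal(a.views["LCC"].pixels, b.views["LCC"].pixels)

    def test_lesion_brighter_than_tissue(self):
        """Mean intensity inside the lesion mask exceeds the mean over
        non-mask tissue pixels (direct measurement on the arrays)."""
        study = generate_study(7, "malignant", 256, 320, 0.8)
        view = next(v for v in synthdata.VIEWS if study.masks[v].present)
        pixels = study.views[view].pixels.astype(float)
        mask = study.masks[view].mask
        tissue = synthdata._tissue_region(320, 256, view)
        assert mask.any()
        assert pixels[mask].mean() > pixels[tissue & ~mask].mean()

    def test_malignant_has_present_mask_both_views_of_one_side(self):
        study = generate_study(5, "malignant", 256, 320, 0.8)
        present = {v for v in synthdata.VIEWS if study.masks[v].present}
        assert present in ({"LCC", "LMLO"}, {"RCC", "RMLO"})

    def test_invariants_pixel_range_and_dtype(self):
        study = generate_study(9, "benign", 128, 160, 0.5)
        for v in synthdata.VIEWS:
            assert study.views[v].pixels.dtype == np.uint16
            lat = "left" if v.startswith("L") else "right"
            assert study.views[v].laterality == lat

    @pytest.mark.parametrize("label,width,height", [
        ("bogus", 256, 320), ("normal", 32, 320), ("normal", 256, 32)])
    def test_rejects_bad_label_or_size(self, label, width, height):
        with pytest.raises(ValueError):
            generate_study(0, label, width, height, 0.8)

    def test_absent_mask_must_be_zero(self):
        with pytest.raises(ValueError):
            LesionMask(np.ones((4, 4), bool), present=False)


class TestGenerateCohort:
    def test_size_conserved_and_counts_sum(self):
        studies, manifest = generate_cohort(3, 100, (0.62, 0.18, 0.20),
                                            width=128, height=160)
        assert len(studies) == 100
        assert manifest["label"].value_counts().sum() == 100

    def test_point_mass_weights(self):
        studies, _ = generate_cohort(3, 50, (0, 0, 1), width=128, height=160)
        assert all(s.label == "malignant" for s in studies)

    def test_malignant_fraction_binomial_bound(self):
        """Malignant count within 3 sd of n*p under binomial sampling."""
        n, p = 500, 0.20
        studies, _ = generate_cohort(5, n, (0.62, 0.18, 0.20),
                                     width=128, height=160)
        k = sum(s.label == "malignant" for s in studies)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 3 * sd

    def test_seed_determinism(self):
        a, ma = generate_cohort(4, 12, width=128, height=160)
        b, mb = generate_cohort(4, 12, width=128, height=160)
        pd.testing.assert_frame_equal(ma, mb)
        np.testing.assert_array_equal(a[0].views["RMLO"].pixels,
                                      b[0].views["RMLO"].pixels)

    def test_rejects_negative_weights_and_tiny_cohorts(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 100, (-0.1, 0.6, 0.5))
        with pytest.raises(ValueError):
            generate_cohort(0, 5, (0.6, 0.2, 0.2))


def _manifest(rows):
    return pd.DataFrame(rows, columns=["subject_id", "exam_date", "birads",
                                       "label", "had_surgery"])


class TestCohortFilter:
    def test_qualifying_pair_returns_later_exam(self):
        m = _manifest([("a", "2015-01-01", 1, "normal", False),
                       ("a", "2016-03-01", 1, "normal", False)])  # 14 months
        assert cohort_filter(m) == [("a", pd.Timestamp("2016-03-01"))]

    def test_short_interval_not_selected(self):
        m = _manifest([("a", "2015-01-01", 1, "normal", False),
                       ("a", "2015-07-01", 1, "normal", False)])  # 6 months
        assert cohort_filter(m) == []

    def test_hand_enumerated_toy_manifest(self):
        """Six subjects covering every rule branch; expected selection
        worked out by hand from the rules."""
        m = _manifest([
            # qualifies: >=365 d, same BI-RADS -> latest kept
            ("p1", "2014-01-01", 2, "benign", False),
            ("p1", "2015-06-01", 2, "benign", False),
            # fails: BI-RADS changed between the two most recent exams
            ("p2", "2014-01-01", 1, "normal", False),
            ("p2", "2015-06-01", 2, "benign", False),
            # fails: only one exam
            ("p3", "2015-01-01", 1, "normal", False),
            # malignant with surgery -> latest (preoperative) exam kept
            ("p4", "2016-02-01", 5, "malignant", True),
            # malignant without surgery -> dropped
            ("p5", "2016-02-01", 4, "malignant", False),
            # fails: pair exactly 364 days apart
            ("p6", "2015-01-01", 3, "benign", False),
            ("p6", "2015-12-31", 3, "benign", False),
        ])
        expected = [("p1", pd.Timestamp("2015-06-01")),
                    ("p4", pd.Timestamp("2016-02-01"))]
        assert sorted(cohort_filter(m)) == expected

    def test_365_day_boundary_inclusive(self):
        m = _manifest([("a", "2015-01-01", 1, "normal", False),
                       ("a", "2016-01-01", 1, "normal", False)])  # exactly 365
        assert len(cohort_filter(m)) == 1

    def test_idempotent_on_selected_subjects(self):
        """Restricting the manifest to the selected subjects' rows and
        re-filtering returns the same selection."""
        m = _manifest([
            ("p1", "2014-01-01", 2, "benign", False),
            ("p1", "2015-06-01", 2, "benign", False),
            ("p2", "2015-01-01", 1, "normal", False),
            ("p4", "2016-02-01", 5, "malignant", True),
        ])
        first = cohort_filter(m)
        chosen = {sid for sid, _ in first}
        again = cohort_filter(m[m["subject_id"].isin(chosen)])
        assert sorted(first) == sorted(again)

    def test_each_subject_contributes_at_most_one_exam(self):
        m = _manifest([("a", "2013-01-01", 1, "normal", False),
                       ("a", "2014-02-01", 1, "normal", False),
                       ("a", "2015-06-01", 1, "normal", False)])
        sel = cohort_filter(m)
        assert len(sel) == 1 and sel[0][1] == pd.Timestamp("2015-06-01")


class TestRoundTrip:
    def test_save_load_cohort(self, tmp_path, small_cohort):
        studies, manifest = small_cohort
        synthdata.save_cohort(studies[:4], manifest.head(4), tmp_path)
        loaded, _ = synthdata.load_cohort(tmp_path)
        assert len(loaded) == 4
        for orig, new in zip(studies[:4], loaded):
            assert orig.label == new.label
            np.testing.assert_array_equal(orig.views["LCC"].pixels,
                                          new.views["LCC"].pixels)
            np.testing.assert_array_equal(orig.masks["LMLO"].mask,
                                          new.masks["LMLO"].mask)
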
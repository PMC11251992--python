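import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscreen.errors import (
    DegeneratePlateError,
    InvalidWellError,
    PlateInvalidError,
    UndefinedZFactorError,
)
from neoscreen.trfret import (
    call_stable_binders,
    percent_deltaf,
    process_plates,
    rfu_ratio,
    robust_zscore,
    z_factor,
)


class TestRfuRatio:
    def test_equal_channels_give_ten_thousand(self):
        assert rfu_ratio(500, 500) == 10_000

    def test_direct_arithmetic(self):
        assert rfu_ratio(200, 400) == 5_000

    def test_zero_donor_channel_is_invalid(self):
        with pytest.raises(InvalidWellError):
            rfu_ratio(100, 0)


class TestPercentDeltaF:
    def test_sample_at_negative_mean_scores_zero(self):
        assert percent_deltaf(1500.0, [1000.0, 2000.0]) == 0.0

    def test_doubling_scores_one_hundred(self):
        assert percent_deltaf(3000.0, [1000.0, 2000.0]) == 100.0

    def test_single_negative_well_rejected(self):
        with pytest.raises(PlateInvalidError):
            percent_deltaf(3000.0, [1500.0])

    def test_scale_invariance_under_common_ratio_factor(self):
        neg = [900.0, 1000.0, 1100.0]
        a = percent_deltaf(1500.0, neg)
        b = percent_deltaf(1500.0 * 7, [x * 7 for x in neg])
        assert a == pytest.approx(b)


class TestRobustZScore:
    def test_sample_at_negative_median_scores_zero(self):
        assert robust_zscore(3.0, [1, 2, 3, 4, 5]) == 0.0

    def test_five_scaled_mads_above_median_scores_five(self):
        # negatives {1..5}: median 3, MAD 1
        assert robust_zscore(3 + 5 * 1.4826, [1, 2, 3, 4, 5]) == pytest.approx(5.0)

    def test_zero_mad_falls_back_to_standard_deviation(self, caplog):
        # MAD of {0,0,0,10} is 0 but sd is not
        z = robust_zscore(5.0, [0.0, 0.0, 0.0, 10.0])
        assert z == pytest.approx(5.0 / np.std([0, 0, 0, 10.0], ddof=1))

    def test_identical_negatives_are_degenerate(self):
        with pytest.raises(DegeneratePlateError):
            robust_zscore(5.0, [2.0, 2.0, 2.0])

    @given(
        shift=st.integers(-1000, 1000),
        neg=st.lists(st.integers(-100, 100), min_size=3, max_size=16),
        sample=st.integers(-100, 100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_translation_invariance(self, shift, neg, sample):
        # small integers are exactly representable, so the shift is lossless
        med = np.median(neg)
        if np.median(np.abs(np.asarray(neg, dtype=float) - med)) == 0:
            return
        a = robust_zscore(sample, neg)
        b = robust_zscore(sample + shift, [x + shift for x in neg])
        assert a == pytest.approx(b, abs=1e-9)


class TestZFactor:
    def test_zero_variance_controls_give_one(self):
        assert z_factor([100.0, 100.0], [0.0, 0.0]) == 1.0

    def test_textbook_value(self):
        # two-point groups with sample sd exactly 5 (mean +/- 5/sqrt(2))
        d = 5 / math.sqrt(2)
        assert z_factor([100 - d, 100 + d], [-d, d]) == pytest.approx(0.7)

    def test_equal_means_undefined(self):
        with pytest.raises(UndefinedZFactorError):
            z_factor([1.0, 3.0], [3.0, 1.0])

    def test_printed_variant_subtracts_sd_terms(self):
        d = 5 / math.sqrt(2)
        pos, neg = [100 - d, 100 + d], [-d, d]
        # equal sds: printed form cancels to 1 regardless of separation
        assert z_factor(pos, neg, as_printed=True) == pytest.approx(1.0)


def _plate(plate_id, neg_ratios, pos_ratios, sample_ratios, allele="A*02:01"):
    rows = []
    wells = iter(f"{r}{c}" for c in range(1, 25) for r in "ABCDEFGHIJKLMNOP")
    for ratio, role, peptide in (
        [(x, "pos_ctrl", "pp65") for x in pos_ratios]
        + [(x, "neg_ctrl_no_peptide", None) for x in neg_ratios]
        + [(x, "sample", f"PEP{i}") for i, x in enumerate(sample_ratios)]
    ):
        rows.append(
            {
                "plate_id": plate_id,
                "well": next(wells),
                "role": role,
                "peptide": peptide,
                "allele": allele,
                "rfu_665": ratio * 500 / 1e4,
                "rfu_615": 500.0,
            }
        )
    return pd.DataFrame(rows)


class TestProcessPlates:
    def test_negative_median_scores_zero_rz(self, rng):
        neg = list(rng.normal(2000, 40, 8))
        samples = list(rng.normal(2000, 40, 40))
        plates = _plate("P1", neg, list(rng.normal(4000, 40, 4)), samples)
        stats, records = process_plates(plates, rz_scale="negatives")
        # recompute the negative wells' %DeltaF median; its RZ is 0 by construction
        assert stats.loc[0, "neg_median_deltaf"] == pytest.approx(
            float(
                np.median((np.array(neg) - np.mean(neg)) / np.mean(neg) * 100)
            )
        )
        # a synthetic sample placed exactly at the negative median scores 0
        med_ratio = float(np.median(neg))
        plates2 = _plate("P1", neg, list(rng.normal(4000, 40, 4)), [med_ratio])
        _, rec2 = process_plates(plates2, rz_scale="negatives")
        assert rec2.loc[0, "rz_score"] == pytest.approx(0.0)

    def test_qc_pass_iff_z_factor_above_threshold(self, rng):
        good = _plate("G", list(rng.normal(2000, 20, 8)),
                      list(rng.normal(6000, 20, 4)), list(rng.normal(2000, 20, 20)))
        bad = _plate("B", list(rng.normal(2000, 800, 8)),
                     list(rng.normal(2600, 800, 4)), list(rng.normal(2000, 800, 20)))
        stats, _ = process_plates(pd.concat([good, bad], ignore_index=True))
        stats = stats.set_index("plate_id")
        assert bool(stats.loc["G", "qc_pass"]) is True
        assert (stats["qc_pass"] == (stats["z_factor"] > 0.4)).all()

    def test_rz_translation_invariant_under_ratio_offset(self, rng):
        neg = rng.normal(2000, 40, 8)
        samples = rng.normal(2100, 40, 40)
        pos = rng.normal(6000, 40, 4)
        a = process_plates(_plate("P", list(neg), list(pos), list(samples)))[1]
        # multiplying every ratio by a constant leaves %DeltaF and RZ unchanged
        b = process_plates(
            _plate("P", list(neg * 3), list(pos * 3), list(samples * 3))
        )[1]
        np.testing.assert_allclose(a["percent_deltaf"], b["percent_deltaf"])
        np.testing.assert_allclose(a["rz_score"], b["rz_score"])

    def test_nonpositive_donor_channel_rejected(self, rng):
        plates = _plate("P", [2000.0] * 8, [4000.0] * 4, [2000.0] * 4)
        plates.loc[3, "rfu_615"] = 0.0
        with pytest.raises(InvalidWellError):
            process_plates(plates)


class TestCallStableBinders:
    def _stats(self, zf):
        return pd.DataFrame(
            {"plate_id": ["P1"], "z_factor": [zf], "qc_pass": [zf > 0.4]}
        )

    def _records(self, rz_scores):
        return pd.DataFrame(
            {
                "peptide": [f"p{i}" for i in range(len(rz_scores))],
                "allele": ["A*02:01"] * len(rz_scores),
                "plate_id": ["P1"] * len(rz_scores),
                "rz_score": rz_scores,
            }
        )

    def test_threshold_is_inclusive(self):
        out = call_stable_binders(self._records([5.0, 4.99]), self._stats(0.6))
        assert list(out["stable_binder"]) == [True, False]

    def test_failed_plate_records_excluded_not_called(self, caplog):
        out = call_stable_binders(self._records([8.0]), self._stats(0.3))
        assert out.empty
        assert "QC-failing" in caplog.text

    def test_raising_threshold_never_grows_binder_set(self):
        records = self._records(list(np.linspace(0, 10, 21)))
        stats = self._stats(0.8)
        previous = None
        for thr in (3.0, 5.0, 7.0):
            binders = set(
                call_stable_binders(records, stats, threshold=thr)
                .query("stable_binder")["peptide"]
            )
            if previous is not None:
                assert binders <= previous
            previous = binders
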
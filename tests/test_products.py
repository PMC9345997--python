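"""Product-distribution representation, grouping and concordance.

The named fixture distributions reproduce the published headline
percentages (AlyV trisaccharide 82.9%, PyAly tetrasaccharide 44.8% /
trisaccharide 21.9%, AlyA trisaccharide 61.1%, AYO24072 disaccharide
92.3%); the minor components are synthetic completions to 100%.
"""

import pytest

from pl7loop import (
    DpClass,
    GroupLabel,
    ProductDistribution,
    concordance,
    group_of,
    main_product,
    normalize_distribution,
    read_distributions,
)
from pl7loop.errors import PairingError, ValidationError
from pl7loop.pipeline import DpPrediction, ScreenResult

ALYV_DIST = ProductDistribution("AlyV", {2: 10.0, 3: 82.9, 4: 7.1})
PYALY_DIST = ProductDistribution("PyAly", {2: 5.0, 3: 21.9, 4: 44.8, 5: 28.3})
ALYA_DIST = ProductDistribution("AlyA", {2: 10.0, 3: 61.1, 4: 20.0, 5: 8.9})
AYO_DIST = ProductDistribution("AYO24072", {2: 92.3, 3: 4.0, 4: 3.7})


def make_prediction(pid, loop1_len):
    from pl7loop import classify_loop1

    screen = ScreenResult(True, frozenset(), 300)
    cls = classify_loop1(loop1_len)
    return DpPrediction(pid, screen, None, loop1_len, cls, "fixture")


class TestNormalize:
    def test_simple(self):
        d = normalize_distribution("x", {2: 10, 3: 90})
        assert d.percents == {2: 10.0, 3: 90.0}

    def test_symmetry(self):
        d = normalize_distribution("x", {3: 1, 4: 1})
        assert d.percents == {3: 50.0, 4: 50.0}

    def test_hand_arithmetic(self):
        d = normalize_distribution("x", {2: 2, 3: 3, 4: 5})
        assert d.percents == {2: 20.0, 3: 30.0, 4: 50.0}

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            normalize_distribution("x", {2: 0.0, 3: 0.0})

    def test_output_sums_to_100_exactly(self):
        d = normalize_distribution("x", {2: 1, 3: 1, 4: 1})
        assert sum(d.percents.values()) == pytest.approx(100.0, abs=1e-9)

    def test_sum_far_from_100_rejected(self):
        with pytest.raises(ValidationError):
            ProductDistribution("x", {2: 40.0, 3: 40.0})


class TestMainProductAndGroup:
    def test_alyv_main_product_dp3(self):
        call = main_product(ALYV_DIST)
        assert call.dp == 3 and not call.tied

    def test_pyaly_main_product_dp4(self):
        assert main_product(PYALY_DIST).dp == 4

    def test_tie_breaks_to_smaller_dp_with_flag(self):
        call = main_product(ProductDistribution("t", {2: 50.0, 3: 50.0}))
        assert call.dp == 2 and call.tied

    def test_alya_tri_di_group(self):
        assert group_of(ALYA_DIST) is GroupLabel.TRI_DI_PREDOMINANT

    def test_ayo_disaccharide_groups_with_tri(self):
        assert main_product(AYO_DIST).dp == 2
        assert group_of(AYO_DIST) is GroupLabel.TRI_DI_PREDOMINANT

    def test_pyaly_larger_oligo_group(self):
        assert group_of(PYALY_DIST) is GroupLabel.LARGER_OLIGO_PREDOMINANT

    def test_group_scale_invariant(self):
        raw = {2: 3.0, 3: 11.0, 4: 6.0}
        base = group_of(normalize_distribution("x", raw))
        for k in (0.01, 1.0, 250.0):
            scaled = {dp: a * k for dp, a in raw.items()}
            assert group_of(normalize_distribution("x", scaled)) is base


class TestConcordance:
    def test_single_concordant_pair(self):
        report = concordance([make_prediction("AlyV", 18)], [ALYV_DIST])
        assert report.agreement == 1.0 and report.n == 1

    def test_three_of_four_concordant(self):
        preds = [
            make_prediction("AlyV", 18),      # SMALL vs TRI_DI -> concordant
            make_prediction("PyAly", 10),     # LARGE vs LARGER -> concordant
            make_prediction("AlyA", 14),      # SMALL vs TRI_DI -> concordant
            make_prediction("AYO24072", 10),  # LARGE vs TRI_DI -> discordant
        ]
        obs = [ALYV_DIST, PYALY_DIST, ALYA_DIST, AYO_DIST]
        report = concordance(preds, obs)
        assert report.agreement == 0.75
        assert report.counts[("SMALL_OLIGO", "TRI_DI_PREDOMINANT")] == 2
        assert report.counts[("LARGE_OLIGO", "LARGER_OLIGO_PREDOMINANT")] == 1
        assert report.counts[("LARGE_OLIGO", "TRI_DI_PREDOMINANT")] == 1

    def test_order_invariant(self):
        preds = [make_prediction("AlyV", 18), make_prediction("PyAly", 10)]
        obs = [ALYV_DIST, PYALY_DIST]
        a = concordance(preds, obs)
        b = concordance(list(reversed(preds)), list(reversed(obs)))
        assert a.agreement == b.agreement and a.counts == b.counts

    def test_unmatched_ids_raise_listing_offenders(self):
        with pytest.raises(PairingError) as exc:
            concordance([make_prediction("AlyV", 18)], [PYALY_DIST])
        assert set(exc.value.offenders) == {"AlyV", "PyAly"}


class TestDistributionFile:
    def test_read_tsv_and_normalize(self, tmp_path):
        p = tmp_path / "dist.tsv"
        p.write_text("e1\t2\t10\ne1\t3\t90\ne2\t4\t1\ne2\t5\t1\n")
        d1, d2 = read_distributions(p)
        assert d1.percents == {2: 10.0, 3: 90.0}
        assert d2.percents == {4: 50.0, 5: 50.0}
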
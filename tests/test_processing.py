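"""Mass matching, migration-time alignment, intensity normalization."""

import numpy as np
import pandas as pd
import pytest

import cemsnorm as cn
from cemsnorm.datatypes import ReferenceDataset
from cemsnorm.simulate import warp_rmse
from conftest import make_matrix


def _ref_from_values(rows, stable=None):
    """Reference with explicit (mz, mt, intensities-per-sample) rows."""
    ids, data = [], {}
    for mz, mt, vals in rows:
        fid = cn.FeatureKey(mz, mt).id
        ids.append(fid)
        data[fid] = vals
    mat = pd.DataFrame.from_dict(data, orient="index",
                                 columns=[f"r{j}" for j in
                                          range(len(rows[0][2]))])
    return ReferenceDataset(matrix=cn.FeatureMatrix(mat),
                            stable=stable or [], mt_window=(840, 3000))


def _pl(rows, sample_id="s"):
    return cn.PeakList(sample_id, pd.DataFrame(
        rows, columns=["mz", "mt", "intensity"]))


class TestMatchMasses:
    def test_close_mass_within_tolerance_matches(self):
        ref = _ref_from_values([(227.111791, 989.758, [5.0, 6.0])])
        pl = _pl([(227.1118, 989.8, 7.0)])
        res = cn.match_masses(pl, ref)
        assert res.n_matched == 1
        assert abs(res.pairs[0][2]) <= 0.01

    def test_outside_tolerance_unmatched(self):
        ref = _ref_from_values([(100.020, 1000.0, [5.0, 6.0]),
                                (300.0, 2000.0, [1.0, 1.0])])
        pl = _pl([(100.000, 1000.0, 7.0), (300.0, 2000.0, 2.0)])
        res = cn.match_masses(pl, ref)
        assert "100.000000/1000.000" in res.unmatched
        assert res.n_matched == 1

    def test_equidistant_tie_goes_to_smaller_mz(self):
        ref = _ref_from_values([(100.004, 1000.0, [5.0, 6.0]),
                                (100.006, 1000.0, [5.0, 6.0])])
        pl = _pl([(100.005, 1000.0, 7.0)])
        res = cn.match_masses(pl, ref, mt_gate=None)
        assert res.pairs[0][1] == "100.004000/1000.000"

    def test_counts_partition_and_determinism(self, reference, qc_cohort):
        pl = qc_cohort.peak_lists[0]
        r1 = cn.match_masses(pl, reference)
        r2 = cn.match_masses(pl, reference)
        assert r1.pairs == r2.pairs
        assert r1.n_matched + len(r1.unmatched) == len(pl)

    def test_no_match_raises(self):
        ref = _ref_from_values([(500.0, 2000.0, [5.0, 6.0])])
        pl = _pl([(100.0, 1000.0, 7.0)])
        with pytest.raises(ValueError, match="incompatible"):
            cn.match_masses(pl, ref)


class TestAlignment:
    def test_identity_warp_is_noop(self, reference, qc_cohort):
        pl = qc_cohort.peak_lists[0]
        match = cn.match_masses(pl, reference)
        aligned, _ = cn.align_migration_times(pl, match.standards_hit,
                                              reference)
        np.testing.assert_allclose(aligned.table["mt"],
                                   pl.table["mt"], atol=0.1)

    @pytest.mark.parametrize("warp", ["constant", "linear"])
    def test_planted_warp_recovered(self, reference, qc_cohort, warp):
        pl = qc_cohort.peak_lists[1]
        mt = pl.table["mt"].to_numpy()
        if warp == "constant":
            warped = pl.with_mt(mt + 10.0)
        else:
            mid = mt.mean()
            warped = pl.with_mt(mid + 1.02 * (mt - mid))
        match = cn.match_masses(warped, reference)
        aligned, _ = cn.align_migration_times(warped, match.standards_hit,
                                              reference)
        std_ids = [s for s, _, _ in match.standards_hit]
        rmse = warp_rmse(qc_cohort.truth, aligned, std_ids)
        assert rmse < 1.0
        if warp == "constant":
            # constant shift recovered everywhere, not only at standards
            assert warp_rmse(qc_cohort.truth, aligned) < 0.5

    def test_idempotent_at_fixed_point(self, reference, qc_cohort):
        pl = qc_cohort.peak_lists[2]
        match = cn.match_masses(pl, reference)
        once, _ = cn.align_migration_times(pl, match.standards_hit,
                                           reference)
        twice, _ = cn.align_migration_times(once, match.standards_hit,
                                            reference)
        np.testing.assert_allclose(twice.table["mt"], once.table["mt"],
                                   atol=0.1)

    def test_standard_order_preserved(self, reference, qc_cohort):
        pl = qc_cohort.peak_lists[3]
        mt = pl.table["mt"].to_numpy()
        warped = pl.with_mt(mt * 1.01)
        match = cn.match_masses(warped, reference)
        aligned, _ = cn.align_migration_times(warped, match.standards_hit,
                                              reference)
        std_ids = [s for s, _, _ in match.standards_hit]
        before = warped.table.loc[std_ids, "mt"].to_numpy()
        after = aligned.table.loc[std_ids, "mt"].to_numpy()
        assert np.array_equal(np.argsort(before), np.argsort(after))

    def test_single_standard_falls_back_to_constant_offset(self):
        ref = _ref_from_values([(100.0, 1000.0, [5.0, 6.0]),
                                (200.0, 1500.0, [2.0, 3.0])],
                               stable=["100.000000/1000.000"])
        pl = _pl([(100.0, 1010.0, 7.0), (200.0, 1510.0, 2.5)])
        match = cn.match_masses(pl, ref)
        aligned, model = cn.align_migration_times(pl, match.standards_hit,
                                                  ref)
        assert model.fallback_constant == pytest.approx(-10.0)
        np.testing.assert_allclose(aligned.table["mt"], [1000.0, 1500.0])


class TestIntensityNormalization:
    def test_sample_at_reference_medians_unchanged(
            self, reference, reference_median_peaklist):
        pl = reference_median_peaklist
        match = cn.match_masses(pl, reference)
        out = cn.normalize_intensities(pl, match.standards_hit, reference,
                                       match=match)
        ratio = out.table["intensity"] / pl.table["intensity"]
        np.testing.assert_allclose(ratio.dropna(), 1.0, atol=0.02)

    def test_doubled_sample_corrected_by_one_log2(
            self, reference, reference_median_peaklist):
        pl = reference_median_peaklist.with_intensity(
            2.0 * reference_median_peaklist.table["intensity"].to_numpy())
        match = cn.match_masses(pl, reference)
        out = cn.normalize_intensities(pl, match.standards_hit, reference,
                                       match=match)
        shift = np.log2(pl.table["intensity"]) - \
            np.log2(out.table["intensity"])
        assert np.nanmean(shift) == pytest.approx(1.0, abs=0.05)

    def test_too_few_standards_rejected(self, reference,
                                        reference_median_peaklist):
        pl = reference_median_peaklist
        match = cn.match_masses(pl, reference)
        with pytest.raises(ValueError, match="standards"):
            cn.normalize_intensities(pl, match.standards_hit[:5], reference,
                                     match=match)

    def test_batch_normalization_reduces_column_median_mad(self, qc_cohort,
                                                           reference):
        pls = qc_cohort.peak_lists[:6]
        fm, _ = cn.process_cohort(pls, reference)
        raw = cn.FeatureMatrix(
            pd.DataFrame({pl.sample_id:
                          pl.table.set_index(pl.table.index)["intensity"]
                          for pl in pls}))
        m_before = cn.variability_metric_M(np.log2(raw.values))
        m_after = cn.variability_metric_M(np.log2(fm.values))
        assert m_after < m_before


def test_process_sample_report_counts(reference, qc_cohort):
    pl = qc_cohort.peak_lists[0]
    out, match, report = cn.process_sample(pl, reference)
    assert report["n_matched"] == match.n_matched
    assert report["n_matched"] + report["n_unmatched"] == report["n_features"]
    assert set(out.feature_ids) <= set(match.pair_map())
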
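"""Deconvolution chain: template, intensity matrix, correlation, assignment."""

import numpy as np
import pytest

import dims2decon as d
from dims2decon.deconvolve import (
    CorrelationMatrix,
    DeconvolutionError,
    PrecursorSet,
    assign_fragments,
    build_intensity_matrix,
    build_template,
    correlation_matrix,
    substitute_precursor,
)
from dims2decon.spectra import Ms2Scan, Peak, ReferenceSpectrum, ScanSeries


def _series_from_peaklists(peaklists, centers=None, width=1.0):
    centers = centers or [100.0 + 0.02 * i for i in range(len(peaklists))]
    scans = tuple(
        Ms2Scan(
            peaks=tuple(sorted(pl, key=lambda p: p.mz)),
            isolation_center=c,
            isolation_width=width,
            scan_index=i,
        )
        for i, (pl, c) in enumerate(zip(peaklists, centers))
    )
    return ScanSeries(scans=scans)


class TestBuildTemplate:
    def test_single_scan_template_keeps_supra_noise_peaks(self):
        series = _series_from_peaklists(
            [[Peak(100.0, 1000.0), Peak(150.0, 10.0)]]
        )
        t = build_template(series)
        assert [p.mz for p in t.peaks] == [100.0, 150.0]
        assert t.source_scan_index == 0

    def test_ground_noise_threshold_removes_sub_03_percent(self):
        # 0.2% of the base peak falls below the 0.3% ground-noise cut
        series = _series_from_peaklists(
            [[Peak(100.0, 1000.0), Peak(150.0, 2.0)]]
        )
        t = build_template(series)
        assert [p.mz for p in t.peaks] == [100.0]

    def test_peak_exactly_at_threshold_retained(self):
        series = _series_from_peaklists(
            [[Peak(100.0, 1000.0), Peak(150.0, 3.0)]]
        )
        t = build_template(series)
        assert [p.mz for p in t.peaks] == [100.0, 150.0]

    def test_blank_subtraction_removes_matching_peak(self):
        # solvent peak at 5% of blank base matches a template peak
        series = _series_from_peaklists(
            [[Peak(100.0, 1000.0), Peak(149.0233, 200.0)]]
        )
        blank = (Peak(149.0233, 5.0), Peak(400.0, 100.0))
        t = build_template(series, blank)
        assert [p.mz for p in t.peaks] == [100.0]

    def test_weak_blank_peak_does_not_subtract(self):
        # blank peak at 0.5% of blank base is below the 1% removal threshold
        series = _series_from_peaklists(
            [[Peak(100.0, 1000.0), Peak(149.0233, 200.0)]]
        )
        blank = (Peak(149.0233, 0.5), Peak(400.0, 100.0))
        t = build_template(series, blank)
        assert [p.mz for p in t.peaks] == [100.0, 149.0233]

    def test_seed_scan_is_max_tic(self):
        series = _series_from_peaklists(
            [[Peak(100.0, 10.0)], [Peak(100.0, 500.0)], [Peak(100.0, 20.0)]]
        )
        t = build_template(series, n_neighbors=0)
        assert t.source_scan_index == 1

    def test_neighbor_window_truncated_at_boundaries(self):
        series = _series_from_peaklists(
            [[Peak(100.0, 500.0)], [Peak(100.0, 400.0)], [Peak(100.0, 300.0)]]
        )
        t = build_template(series, n_neighbors=10)  # seed 0, window [0, 3)
        assert t.peaks[0].intensity == pytest.approx(400.0)  # mean of 3 scans

    def test_empty_series_errors(self):
        with pytest.raises(DeconvolutionError):
            build_template(ScanSeries(scans=()))


class TestIntensityMatrix:
    def test_matches_simulator_ground_truth(self, noiseless_run):
        cfg, series, truth, _, result = noiseless_run
        m = result.intensity_matrix
        for pid, mz in enumerate(m.peak_mzs):
            key = min(truth.noiseless, key=lambda k: abs(k - mz))
            if abs(key - mz) > 0.002:
                continue  # blank peak rows are not in the ground truth
            np.testing.assert_allclose(
                m.values[pid], truth.noiseless[key], rtol=1e-9
            )

    def test_absent_peak_gives_zero_cell(self):
        series = _series_from_peaklists(
            [[Peak(100.0, 1000.0), Peak(150.0, 500.0)], [Peak(100.0, 800.0)]]
        )
        t = build_template(series, n_neighbors=0)
        m = build_intensity_matrix(t, series)
        row = list(m.peak_mzs).index(150.0)
        assert m.values[row, 1] == 0.0

    def test_blank_removed_peak_has_no_row(self):
        series = _series_from_peaklists(
            [[Peak(100.0, 1000.0), Peak(149.0233, 200.0)]]
        )
        blank = (Peak(149.0233, 50.0),)
        t = build_template(series, blank)
        m = build_intensity_matrix(t, series)
        assert 149.0233 not in list(m.peak_mzs)


class TestCorrelationMatrix:
    def test_brute_force_pearson_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0.1, 100.0, size=(10, 20))
        m = d.IntensityMatrix(
            values=x, peak_mzs=np.arange(10, dtype=float) + 100,
            scan_centers=np.arange(20, dtype=float),
        )
        c = correlation_matrix(m)
        for i in range(10):
            for j in range(10):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi * xj).sum() / np.sqrt(
                    (xi**2).sum() * (xj**2).sum()
                )
                assert c.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        m = d.IntensityMatrix(
            values=rng.uniform(1, 10, (4, 6)),
            peak_mzs=np.arange(4, dtype=float) + 100,
            scan_centers=np.arange(6, dtype=float),
        )
        assert np.allclose(np.diag(correlation_matrix(m).values), 1.0)

    def test_anticorrelated_rows(self):
        base = np.array([1.0, 5.0, 9.0, 5.0, 1.0, 3.0])
        neg = base.max() + base.min() - base  # exact negation of centered values
        m = d.IntensityMatrix(
            values=np.vstack([base, neg]),
            peak_mzs=np.array([100.0, 200.0]),
            scan_centers=np.arange(6, dtype=float),
        )
        c = correlation_matrix(m)
        assert c.values[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_row_is_undefined_not_zero(self):
        m = d.IntensityMatrix(
            values=np.vstack([np.ones(6), np.arange(6, dtype=float) + 1]),
            peak_mzs=np.array([100.0, 200.0]),
            scan_centers=np.arange(6, dtype=float),
        )
        c = correlation_matrix(m)
        assert np.isnan(c.values[0, 1])
        assert not c.is_defined(0, 1)

    def test_sparse_support_row_is_undefined(self):
        sparse = np.zeros(8)
        sparse[3] = 5.0
        sparse[4] = 2.0  # only 2 nonzero scans: below the support minimum
        m = d.IntensityMatrix(
            values=np.vstack([sparse, np.arange(8, dtype=float) + 1]),
            peak_mzs=np.array([100.0, 200.0]),
            scan_centers=np.arange(8, dtype=float),
        )
        c = correlation_matrix(m)
        assert np.isnan(c.values[0, 1])

    def test_too_few_scans_errors(self):
        m = d.IntensityMatrix(
            values=np.ones((2, 2)),
            peak_mzs=np.array([100.0, 200.0]),
            scan_centers=np.arange(2, dtype=float),
        )
        with pytest.raises(DeconvolutionError):
            correlation_matrix(m)


def _corr_from_values(values, mzs, centroids):
    return CorrelationMatrix(
        values=np.asarray(values, dtype=float),
        peak_mzs=np.asarray(mzs, dtype=float),
        profile_centroids=np.asarray(centroids, dtype=float),
    )


class TestAssignFragments:
    def test_higher_correlation_wins(self):
        # peaks: 0=P1 anchor, 1=P2 anchor, 2=fragment
        vals = [[1.0, 0.2, 0.9], [0.2, 1.0, 0.3], [0.9, 0.3, 1.0]]
        corr = _corr_from_values(vals, [342.0, 342.05, 150.0], [342.0, 342.05, 342.0])
        pset = PrecursorSet(entries=(("P1", 0, False), ("P2", 1, False)))
        assert assign_fragments(corr, pset) == {2: "P1"}

    def test_tie_breaks_to_nearest_profile_centroid(self, caplog):
        vals = [[1.0, 0.5, 0.8], [0.5, 1.0, 0.8], [0.8, 0.8, 1.0]]
        # fragment's profile centroid sits at the m/z of P2's anchor
        corr = _corr_from_values(vals, [342.0, 342.05, 150.0], [342.0, 342.05, 342.05])
        pset = PrecursorSet(entries=(("P1", 0, False), ("P2", 1, False)))
        import logging

        with caplog.at_level(logging.INFO, logger="dims2decon.deconvolve"):
            out = assign_fragments(corr, pset)
        assert out == {2: "P2"}
        assert any("tie" in r.message for r in caplog.records)

    def test_all_undefined_goes_to_unassigned_pool(self, caplog):
        vals = [[1.0, 0.2, np.nan], [0.2, 1.0, np.nan], [np.nan, np.nan, np.nan]]
        corr = _corr_from_values(vals, [342.0, 342.05, 150.0], [342.0, 342.05, np.nan])
        pset = PrecursorSet(entries=(("P1", 0, False), ("P2", 1, False)))
        out = assign_fragments(corr, pset)
        assert out == {2: None}

    def test_noiseless_assignment_matches_ground_truth(self):
        cfg = d.two_isobar_preset(0.05, n_shared=0, plan=d.build_plan(342.0))
        series, truth = d.simulate_series(cfg)
        res = d.deconvolute(series, cfg.blank_peaks, dict(truth.precursor_mzs))
        acc = d.assignment_accuracy(
            res.assignments, res.correlation.peak_mzs, truth.owner
        )
        assert acc == 1.0

    def test_empty_precursor_set_rejected(self):
        with pytest.raises(ValueError):
            PrecursorSet(entries=())


class TestSubstitutePrecursor:
    @pytest.fixture()
    def template(self):
        series = _series_from_peaklists(
            [[Peak(120.0, 300.0), Peak(150.0, 800.0), Peak(200.0, 400.0)]]
        )
        return build_template(series)

    def test_most_intense_known_fragment_chosen(self, template):
        ref = ReferenceSpectrum(
            compound_id="c", precursor_mz_theoretical=342.0,
            peaks=(Peak(150.0, 90.0), Peak(200.0, 100.0), Peak(342.0, 10.0)),
        )
        # 200.0 is the most intense reference fragment present in the template
        pid = substitute_precursor(template, ref)
        assert template.peaks[pid].mz == 200.0

    def test_falls_back_to_next_fragment(self, template):
        ref = ReferenceSpectrum(
            compound_id="c", precursor_mz_theoretical=342.0,
            peaks=(Peak(150.0, 50.0), Peak(300.0, 100.0)),
        )
        pid = substitute_precursor(template, ref)
        assert template.peaks[pid].mz == 150.0

    def test_no_fragment_in_template_errors(self, template):
        ref = ReferenceSpectrum(
            compound_id="c", precursor_mz_theoretical=342.0,
            peaks=(Peak(300.0, 100.0),),
        )
        with pytest.raises(DeconvolutionError):
            substitute_precursor(template, ref)

    def test_substitution_invoked_end_to_end_when_precursor_absent(self):
        # fully fragmented precursors: no surviving precursor ion in MS2
        plan = d.build_plan(342.0)
        pre = d.PrecursorModel(
            precursor_id="P1", mz=341.976, base_intensity=1e6,
            fragments=((84.0444, 0.5), (158.0812, 0.5)),
        )
        cfg = d.SimConfig(plan=plan, precursors=(pre,),
                          isotopologue_rel_abundance=0.0)
        series, truth = d.simulate_series(cfg)
        ref = ReferenceSpectrum(
            compound_id="P1", precursor_mz_theoretical=341.976,
            peaks=(Peak(84.0444, 50.0), Peak(158.0812, 50.0)),
        )
        res = d.deconvolute(
            series, (), {"P1": 341.976}, references={"P1": ref}
        )
        assert res.spectra[0].is_substitute
        assert res.precursors.entries[0][2] is True

    def test_missing_precursor_without_reference_errors(self):
        plan = d.build_plan(342.0)
        pre = d.PrecursorModel(
            precursor_id="P1", mz=341.976, base_intensity=1e6,
            fragments=((84.0444, 1.0),),
        )
        cfg = d.SimConfig(plan=plan, precursors=(pre,),
                          isotopologue_rel_abundance=0.0)
        series, _ = d.simulate_series(cfg)
        with pytest.raises(DeconvolutionError):
            d.deconvolute(series, (), {"P1": 341.976})


class TestDeconvolutePartition:
    def test_every_template_peak_in_exactly_one_bucket(self, noiseless_run):
        *_, result = noiseless_run
        anchor_ids = set(result.precursors.peak_ids)
        assigned = set(result.assignments)
        assert anchor_ids.isdisjoint(assigned)
        assert anchor_ids | assigned == set(range(len(result.template)))
        recon_total = sum(len(s.peaks) for s in result.spectra)
        assert recon_total + len(result.unassigned_peak_ids) == len(
            result.template
        )

    def test_single_precursor_gets_every_template_peak(self):
        plan = d.build_plan(342.0)
        pre = d.PrecursorModel(
            precursor_id="P1", mz=341.976, base_intensity=1e6,
            fragments=((84.0444, 0.3), (158.0812, 0.2)),
        )
        cfg = d.SimConfig(plan=plan, precursors=(pre,),
                          isotopologue_rel_abundance=0.0)
        series, _ = d.simulate_series(cfg)
        res = d.deconvolute(series, (), {"P1": 341.976})
        assert len(res.spectra) == 1
        assert len(res.spectra[0].peaks) == len(res.template)
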
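import math

import numpy as np
import pytest
from sklearn.base import clone

from sparsesig.calibration import Calibration, CutoffCurve, CutoffRegression, calibrate
from sparsesig.channels import CA_AA_CHANNELS
from sparsesig.detection import (
    GcvSignatureDetector,
    SampleCall,
    bh_adjust,
    call_sample,
    chisq_pvalue,
    cohort_permutation_fdr,
    expected_score_from_cohort,
    run_cohort,
)
from sparsesig.refit import simulate_spectrum
from sparsesig.spectrum import Spectrum96, ca_aa_fraction


def _flat_calibration(cut18=0.2, cut38=None, names=()):
    """Hand-built calibration with constant cutoffs, for branch logic tests."""
    curve18 = CutoffCurve("SBS18", [1, 10_000], [cut18, cut18], reps=1)
    reg18 = CutoffRegression("SBS18", [cut18, 0, 0, 0, 0], 1.0)
    curve38 = reg38 = None
    if cut38 is not None:
        curve38 = CutoffCurve("SBS38", [1, 10_000], [cut38, cut38], reps=1)
        reg38 = CutoffRegression("SBS38", [cut38, 0, 0, 0, 0], 1.0)
    return Calibration(
        curve_primary=curve18,
        regression_primary=reg18,
        curve_skin=curve38,
        regression_skin=reg38,
        signature_names=tuple(names),
    )


@pytest.fixture(scope="module")
def small_calibration(cosmic_catalog):
    """Simulated calibration on reduced grids, shared across this module."""
    return calibrate(
        cosmic_catalog,
        seed=11,
        curve_reps=300,
        curve_counts=[10, 30, 100, 300, 1000],
        surface_reps=200,
        surface_contribs=[0.1, 0.3, 0.5, 0.7, 0.9],
        surface_counts=[10, 50, 120, 250],
    )


class TestCallSample:
    def test_below_ten_mutations_not_evaluable(self, cosmic_catalog, small_calibration, rng):
        spectrum = simulate_spectrum({"GCVsig": 1.0}, cosmic_catalog, 9, rng)
        call = call_sample(spectrum, "GI", cosmic_catalog, small_calibration)
        assert not call.evaluable
        assert not call.positive

    def test_strong_spike_in_is_positive(self, cosmic_catalog, small_calibration):
        rng = np.random.default_rng(42)
        spectrum = simulate_spectrum(
            {"GCVsig": 0.9, "SBS5": 0.1}, cosmic_catalog, 100, rng
        )
        call = call_sample(spectrum, "GI", cosmic_catalog, small_calibration)
        assert call.evaluable
        assert call.positive
        assert call.gcv_score > 0.5

    def test_pure_background_is_negative(self, cosmic_catalog, small_calibration):
        rng = np.random.default_rng(43)
        spectrum = simulate_spectrum({"SBS5": 1.0}, cosmic_catalog, 100, rng)
        call = call_sample(spectrum, "GI", cosmic_catalog, small_calibration)
        assert call.evaluable
        assert not call.positive
        assert call.gcv_score < 0.1

    def test_skin_requires_both_cutoffs(self):
        # the score clears the primary cutoff (0) but cannot clear the skin
        # cutoff (1), so the conjunction rule blocks the skin call only
        counts = np.zeros(96, dtype=int)
        counts[list(CA_AA_CHANNELS)] = 5  # 20 mutations, all CA>AA
        spectrum = Spectrum96(counts)
        calib = _flat_calibration(cut18=0.0, cut38=1.0)
        skin_call = call_sample(spectrum, "SKIN", None_catalog(spectrum), calib)
        assert skin_call.gcv_score > 0.0
        assert not skin_call.positive
        other_call = call_sample(spectrum, "GI", None_catalog(spectrum), calib)
        assert other_call.positive

    def test_regression_path_used_when_ca_aa_above_ten(self, cosmic_catalog):
        calib = _flat_calibration(cut18=0.3)
        rng = np.random.default_rng(44)
        spectrum = simulate_spectrum({"GCVsig": 1.0}, cosmic_catalog, 50, rng)
        assert ca_aa_fraction(spectrum).ca_aa_count > 10
        call = call_sample(spectrum, "GI", cosmic_catalog, calib)
        # flat regression and flat curve agree here; cutoff must be the constant
        assert call.cutoff_sbs18 == pytest.approx(0.3)

    def test_catalog_mismatch_is_an_error(self, cosmic_catalog, disjoint_catalog, small_calibration, rng):
        spectrum = simulate_spectrum({"SBS5": 1.0}, cosmic_catalog, 20, rng)
        with pytest.raises(ValueError, match="different signature catalog"):
            call_sample(spectrum, "GI", disjoint_catalog.subset(["SBS5", "SBS18", "GCVsig"]), small_calibration)


def None_catalog(spectrum):
    """A minimal catalog whose focal signature explains the test spectrum."""
    from sparsesig.catalog_io import SignatureCatalog

    probs = np.zeros((96, 2))
    probs[list(CA_AA_CHANNELS), 0] = 0.25
    probs[:, 1] = 1.0 / 96
    return SignatureCatalog(["GCVsig", "SBS5"], probs)


class TestChisqPvalue:
    def _call(self, score, n):
        return SampleCall(
            sample_id="S",
            n=n,
            gcv_score=score,
            ca_aa=ca_aa_fraction(Spectrum96()),
            cutoff_sbs18=0.1,
            cutoff_sbs38=None,
            evaluable=True,
            positive=False,
        )

    def test_observed_equals_expected_gives_p_one(self):
        assert chisq_pvalue(self._call(0.3, 100), 0.3) == pytest.approx(1.0)

    def test_worked_example_statistic_and_p(self):
        # observed (30, 70) vs expected (20, 80): statistic 10^2/20 + 10^2/80 = 6.25
        p = chisq_pvalue(self._call(0.3, 100), 0.2)
        # independent 1-df upper tail: p = erfc(sqrt(stat / 2))
        assert p == pytest.approx(math.erfc(math.sqrt(6.25 / 2)), rel=1e-12)

    def test_symmetric_in_category_order(self):
        assert chisq_pvalue(self._call(0.3, 100), 0.2) == pytest.approx(
            chisq_pvalue(self._call(0.7, 100), 0.8)
        )

    def test_not_evaluable_is_an_error(self):
        call = self._call(0.3, 100)
        call.evaluable = False
        with pytest.raises(ValueError):
            chisq_pvalue(call, 0.2)

    def test_degenerate_expectation_is_an_error(self):
        with pytest.raises(ValueError):
            chisq_pvalue(self._call(0.3, 100), 1.0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.001, 0.5]), [0.002, 0.5])

    def test_returned_in_input_order_and_monotone(self, rng):
        p = rng.random(25)
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        # adjusted values preserve the ordering of raw p-values
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestExpectedScore:
    def test_orthogonal_average_gives_zero(self, disjoint_catalog):
        avg = np.zeros(96)
        avg[72:96] = 1 / 24  # SBS5 block only
        score = expected_score_from_cohort(
            avg, 50, disjoint_catalog, reps=20, rng=np.random.default_rng(1)
        )
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_single_rep_deterministic(self, cosmic_catalog):
        avg = cosmic_catalog.column("SBS5")
        a = expected_score_from_cohort(
            avg, 30, cosmic_catalog, reps=1, rng=np.random.default_rng(3)
        )
        b = expected_score_from_cohort(
            avg, 30, cosmic_catalog, reps=1, rng=np.random.default_rng(3)
        )
        assert a == b

    def test_concentrates_at_large_n(self, cosmic_catalog):
        from sparsesig.refit import fit_exposures

        avg = 0.5 * cosmic_catalog.column("SBS5") + 0.5 * cosmic_catalog.column("SBS18")
        sampled = expected_score_from_cohort(
            avg, 10_000, cosmic_catalog, reps=100, rng=np.random.default_rng(4)
        )
        exact_counts = np.rint(avg * 10_000).astype(int)
        exact = fit_exposures(Spectrum96(exact_counts), cosmic_catalog).get("GCVsig")
        assert abs(sampled - exact) < 0.02


class TestCohortPermutationFdr:
    def test_orthogonal_cohort_gives_zero_fdr(self, disjoint_catalog):
        counts = np.zeros(96, dtype=int)
        counts[80] = 30  # SBS5 block
        spectra = [Spectrum96(counts)] * 5
        calib = _flat_calibration(cut18=0.2)
        est = cohort_permutation_fdr(
            spectra,
            ["GI"] * 5,
            disjoint_catalog,
            calib,
            rng=np.random.default_rng(0),
        )
        assert est.permutation_positive_counts == [0] * 10
        assert est.estimated_fdr == 0.0

    def test_reproducible_given_seed(self, cosmic_catalog, small_calibration, rng):
        spectra = [
            simulate_spectrum({"SBS18": 0.95, "SBS5": 0.05}, cosmic_catalog, 60, rng)
            for _ in range(8)
        ]
        kwargs = dict(
            cancer_groups=["GI"] * 8,
            catalog=cosmic_catalog,
            calibration=small_calibration,
        )
        a = cohort_permutation_fdr(spectra, rng=np.random.default_rng(7), **kwargs)
        b = cohort_permutation_fdr(spectra, rng=np.random.default_rng(7), **kwargs)
        assert a.permutation_positive_counts == b.permutation_positive_counts

    def test_no_evaluable_samples_is_an_error(self, cosmic_catalog, small_calibration):
        counts = np.zeros(96, dtype=int)
        counts[0] = 3
        with pytest.raises(ValueError):
            cohort_permutation_fdr(
                [Spectrum96(counts)],
                ["GI"],
                cosmic_catalog,
                small_calibration,
                rng=np.random.default_rng(0),
            )


@pytest.fixture(scope="module")
def cohort_files(tmp_path_factory, cosmic_catalog):
    from sparsesig.synthetic import CohortSimSpec, write_cohort

    spec = CohortSimSpec(
        n_samples=120,
        spike_in_fraction=2 / 120,
        spike_in_exposure=0.85,
        seed=21,
    )
    out = tmp_path_factory.mktemp("cohort")
    return write_cohort(spec, cosmic_catalog, out)


class TestRunCohort:
    def test_spike_ins_detected_and_output_written(
        self, cohort_files, small_calibration, tmp_path
    ):
        import pandas as pd

        from sparsesig.detection import RunConfig

        out = tmp_path / "calls.tsv"
        config = RunConfig(seed=3, expected_reps=200, fdr_repeats=3)
        calls, fdr = run_cohort(
            cohort_files["mutations"],
            cohort_files["catalog"],
            small_calibration,
            out_path=out,
            config=config,
        )
        truth = pd.read_csv(cohort_files["truth"], sep="\t")
        spiked = set(truth[truth["spiked"]]["sample_id"])
        called = set(calls[calls["positive"]]["sample_id"])
        assert spiked <= called
        assert out.exists()
        # sorted by score descending
        assert np.all(np.diff(calls["gcv_score"].to_numpy()) <= 1e-12)
        # evaluable samples carry p-values, BH-adjusted >= raw
        ev = calls[calls["evaluable"]]
        assert ev["p_value"].notna().all()
        assert np.all(ev["p_adjusted"] >= ev["p_value"] - 1e-12)
        assert fdr.observed_positive_count == len(called)

    def test_rerun_is_byte_identical(self, cohort_files, small_calibration, tmp_path):
        from sparsesig.detection import RunConfig

        outs = []
        for name in ("a.tsv", "b.tsv"):
            out = tmp_path / name
            run_cohort(
                cohort_files["mutations"],
                cohort_files["catalog"],
                small_calibration,
                out_path=out,
                config=RunConfig(seed=3, expected_reps=50, fdr_repeats=2),
            )
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_empty_cohort_is_an_error(self, tmp_path, cohort_files, small_calibration):
        import pandas as pd

        empty = tmp_path / "empty.tsv"
        pd.read_csv(cohort_files["mutations"], sep="\t").head(0).to_csv(
            empty, sep="\t", index=False
        )
        with pytest.raises(Exception):
            run_cohort(empty, cohort_files["catalog"], small_calibration)


class TestGcvSignatureDetector:
    def test_fit_predict_round_trip(self, cosmic_catalog):
        det = GcvSignatureDetector(
            cosmic_catalog,
            curve_reps=200,
            curve_counts=[10, 100, 1000],
            surface_reps=100,
            surface_contribs=[0.1, 0.5, 0.9],
            surface_counts=[10, 100, 250],
            random_state=5,
        )
        det.fit()
        rng = np.random.default_rng(6)
        spike = simulate_spectrum({"GCVsig": 0.9, "SBS5": 0.1}, cosmic_catalog, 80, rng)
        null = simulate_spectrum({"SBS5": 1.0}, cosmic_catalog, 80, rng)
        X = np.stack([spike.counts, null.counts])
        pred = det.predict(X, cancer_groups=["GI", "GI"])
        assert pred.tolist() == [True, False]
        scores = det.score_samples(X)
        assert scores[0] > scores[1]
        margins = det.decision_function(X, cancer_groups=["GI", "GI"])
        assert margins[0] > 0 > margins[1]

    def test_matches_call_sample(self, cosmic_catalog, small_calibration):
        det = GcvSignatureDetector(cosmic_catalog)
        det.calibration_ = small_calibration
        det.curve_primary_ = small_calibration.curve_primary
        rng = np.random.default_rng(8)
        spectrum = simulate_spectrum({"SBS18": 0.95, "SBS5": 0.05}, cosmic_catalog, 70, rng)
        single = call_sample(spectrum, "SKIN", cosmic_catalog, small_calibration)
        pred = det.predict(spectrum.counts[None, :], cancer_groups=["SKIN"])
        assert bool(pred[0]) == single.positive

    def test_sklearn_protocol(self, cosmic_catalog):
        det = GcvSignatureDetector(cosmic_catalog, curve_reps=17)
        cloned = clone(det)
        assert cloned.get_params()["curve_reps"] == 17
        with pytest.raises(ValueError, match="not fitted"):
            cloned.predict(np.zeros((1, 96)))
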
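"""FIC filtration, target-decoy FDR, ROC sweeps, confidence QC, cross-referencing."""

import numpy as np
import pytest

from chima.chem import PROTON_MASS, PeptideForm
from chima.search import fragment_ions, score_and_rank
from chima.simulate import SimulationConfig, simulate_spectrum
from chima.spectra import Spectrum
from chima.validation import (
    classify_confidence,
    cross_reference,
    filter_fic,
    roc_compare,
    target_decoy_fdr,
)

from oracles import brute_force_fdr_threshold


def make_psm(scan_id="s", fic=1.0, score=10.0, is_decoy=False, form=None,
             precursor_mz=500.0, rt=10.0):
    """Minimal PSM stand-in for filter/FDR/ROC tests."""
    from chima.search import PSM

    return PSM(
        scan_id=scan_id,
        form=form if form is not None else PeptideForm("ACDEFGHIK"),
        charge=2,
        precursor_mz=precursor_mz,
        retention_time=rt,
        matched_positions=frozenset(),
        assignments={},
        fic=fic,
        n_matched_ions=int(fic * 16),
        explained_intensity=0.0,
        rank_score=score,
        delta_score=score,
        precursor_error_ppm=0.0,
        is_decoy=is_decoy,
    )


class TestFilterFic:
    def test_inclusive_boundary(self):
        psms = [make_psm(fic=0.5), make_psm(fic=0.4375)]
        kept = filter_fic(psms, 0.5)
        assert kept == [psms[0]]

    def test_cutoff_zero_keeps_everything(self):
        psms = [make_psm(fic=f) for f in (0.0, 0.2, 0.9)]
        assert filter_fic(psms, 0.0) == psms

    def test_cutoff_one_keeps_complete_ladders_only(self):
        psms = [make_psm(fic=1.0), make_psm(fic=0.9999)]
        assert filter_fic(psms, 1.0) == [psms[0]]

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            filter_fic([], 1.5)


class TestTargetDecoyFdr:
    def test_low_decoy_passes_everything(self):
        res = target_decoy_fdr(target_scores=[10, 9, 8], decoy_scores=[1], level=0.01)
        assert res.threshold == 8
        assert res.achieved_fdr == 0.0

    def test_small_dataset_failure_mode(self):
        """One well-scoring decoy among ten targets: only the single target
        above the decoy survives a 1% level."""
        targets = list(range(1, 11))
        res = target_decoy_fdr(target_scores=targets, decoy_scores=[9.5], level=0.01)
        assert res.threshold == 10
        assert sum(s >= res.threshold for s in targets) == 1

    def test_identical_distributions_nothing_passes(self):
        scores = [5, 4, 3, 2, 1]
        res = target_decoy_fdr(target_scores=scores, decoy_scores=scores, level=0.01)
        assert res.threshold is None

    def test_no_decoys_flagged(self):
        res = target_decoy_fdr(target_scores=[3, 2], decoy_scores=[], level=0.01)
        assert res.no_decoys and res.threshold is None

    def test_qvalues_monotone_in_score(self, rng):
        t = rng.uniform(0, 20, size=50)
        d = rng.uniform(0, 20, size=50)
        res = target_decoy_fdr(target_scores=t, decoy_scores=d, level=0.05)
        order = np.argsort(t)
        q = res.qvalues_targets[order]
        assert np.all(np.diff(q) <= 1e-12)

    @pytest.mark.parametrize("level", [0.01, 0.05, 0.2])
    def test_matches_exhaustive_sweep(self, rng, level):
        """Threshold agrees with a brute-force sweep over every distinct
        score on random instances."""
        for _ in range(100):
            n_t = int(rng.integers(1, 60))
            n_d = int(rng.integers(1, 40))
            t = np.round(rng.uniform(0, 15, size=n_t), 2).tolist()
            d = np.round(rng.uniform(0, 15, size=n_d), 2).tolist()
            res = target_decoy_fdr(target_scores=t, decoy_scores=d, level=level)
            expected = brute_force_fdr_threshold(t, d, level)
            assert res.threshold == expected


class TestRocCompare:
    @pytest.fixture()
    def labeled_psms(self):
        psms = []
        labels = {}
        # 10 true PSMs, high score & full coverage
        for i in range(10):
            p = make_psm(scan_id=f"t{i}", fic=0.8, score=20 - i)
            psms.append(p)
            labels[(p.scan_id, p.form.key())] = True
        # 50 false PSMs, 1 of which sneaks over 50% FIC (2%)
        for i in range(50):
            p = make_psm(scan_id=f"f{i}", fic=0.55 if i == 0 else 0.2, score=5 - i * 0.05)
            psms.append(p)
            labels[(p.scan_id, p.form.key())] = False
        psms.append(make_psm(scan_id="d0", score=9.5, is_decoy=True))
        return psms, labels

    def test_curves_span_unit_square_and_are_monotone(self, labeled_psms):
        psms, labels = labeled_psms
        for curve in roc_compare(psms, labels):
            fprs = [p[1] for p in curve.points]
            tprs = [p[2] for p in curve.points]
            assert (fprs[0], tprs[0]) == (0.0, 0.0)
            assert (fprs[-1], tprs[-1]) == (1.0, 1.0)
            assert all(b >= a for a, b in zip(fprs, fprs[1:]))
            assert all(b >= a for a, b in zip(tprs, tprs[1:]))

    def test_fic_sweep_point_at_half_coverage(self, labeled_psms):
        """With all true PSMs above 50% coverage and 2% of false ones,
        the 0.5-cutoff point sits at (0.02, 1.0)."""
        psms, labels = labeled_psms
        _, fic_curve = roc_compare(psms, labels)
        point = next(p for p in fic_curve.points if abs(p[0] - 0.5) < 1e-9)
        assert point[1] == pytest.approx(0.02)
        assert point[2] == pytest.approx(1.0)

    def test_fic_dominates_fdr_with_planted_decoy(self, labeled_psms):
        psms, labels = labeled_psms
        fdr_curve, fic_curve = roc_compare(psms, labels)

        def tpr_at(curve, fpr):
            return max((p[2] for p in curve.points if p[1] <= fpr), default=0.0)

        for fpr in (0.0, 0.02, 0.1, 0.5, 1.0):
            assert tpr_at(fic_curve, fpr) >= tpr_at(fdr_curve, fpr) - 1e-12


class TestClassifyConfidence:
    def _psm_and_spectrum(self, mods, noise=(), isotopes=True):
        form = PeptideForm("KSTGGKAPR", mods=((1, mods["la"]),))
        config = SimulationConfig(seed=5, isotopes=isotopes, noise_peaks=0)
        rng = np.random.default_rng(5)
        sp = simulate_spectrum(form, config, rng, "qc")
        if noise:
            peaks = np.vstack([sp.peaks, np.array(noise)])
            sp = Spectrum("qc", sp.precursor_mz, 2, sp.retention_time, peaks)
        (psm,) = score_and_rank(sp, [form])
        return psm, sp

    def test_clean_spectrum_is_high(self, mods):
        psm, sp = self._psm_and_spectrum(mods)
        assert classify_confidence(psm, sp) == "high"

    def test_loud_peak_above_precursor_demotes(self, mods):
        psm, sp = self._psm_and_spectrum(mods, noise=[(1100.0, 2e4)])
        assert sp.precursor_mz < 1100.0
        assert classify_confidence(psm, sp) == "moderate"

    def test_missing_isotope_companions_demote(self, mods):
        psm, sp = self._psm_and_spectrum(mods, isotopes=False)
        assert classify_confidence(psm, sp) == "moderate"

    def test_quiet_noise_tolerated(self, mods):
        psm, sp = self._psm_and_spectrum(mods, noise=[(1100.0, 10.0)])
        assert classify_confidence(psm, sp) == "high"


class TestCrossReference:
    def _accepted(self, mods, keys, dataset):
        psms = []
        for i, form in enumerate(keys):
            psms.append(
                make_psm(
                    scan_id=f"{dataset}.{i}",
                    form=form,
                    precursor_mz=(form.neutral_mass + 2 * PROTON_MASS) / 2,
                    rt=10.0 + i,
                )
            )
        return psms

    def _spectra_for(self, forms, dataset):
        out = []
        for i, form in enumerate(forms):
            mz = (form.neutral_mass + 2 * PROTON_MASS) / 2
            out.append(
                Spectrum(f"{dataset}.raw{i}", mz, 2, 10.0 + i,
                         np.array([[200.0, 10.0]]))
            )
        return out

    @pytest.fixture()
    def twelve_forms(self, mods, histones):
        from chima.simulate import benchmark_form_pool

        pool, _ = benchmark_form_pool(mods)
        return pool[:12]

    def test_identical_datasets_zero_loss(self, mods, twelve_forms):
        runs = {
            "A": self._accepted(mods, twelve_forms, "A"),
            "B": self._accepted(mods, twelve_forms, "B"),
        }
        spectra = {
            "A": self._spectra_for(twelve_forms, "A"),
            "B": self._spectra_for(twelve_forms, "B"),
        }
        result = cross_reference(runs, spectra)
        assert result.loss_rate == {"A": 0.0, "B": 0.0}

    def test_loss_rate_arithmetic(self, mods, twelve_forms):
        """Dataset B accepts 9 of A's 12 forms but recorded all 12 spectra:
        3 missed / 12 verified = 25% loss."""
        runs = {
            "A": self._accepted(mods, twelve_forms, "A"),
            "B": self._accepted(mods, twelve_forms[:9], "B"),
        }
        spectra = {
            "A": self._spectra_for(twelve_forms, "A"),
            "B": self._spectra_for(twelve_forms, "B"),
        }
        result = cross_reference(runs, spectra)
        assert result.loss_rate["A"] == 0.0
        assert result.loss_rate["B"] == pytest.approx(0.25)

    def test_absent_precursor_not_counted_missed(self, mods, twelve_forms):
        runs = {
            "A": self._accepted(mods, twelve_forms, "A"),
            "B": self._accepted(mods, twelve_forms[:9], "B"),
        }
        spectra = {
            "A": self._spectra_for(twelve_forms, "A"),
            "B": self._spectra_for(twelve_forms[:9], "B"),  # no trace of the 3
        }
        result = cross_reference(runs, spectra)
        assert result.loss_rate["B"] == 0.0

    def test_needs_two_datasets(self, mods, twelve_forms):
        with pytest.raises(ValueError):
            cross_reference({"A": []}, {"A": []})
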
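"""Theoretical fragments, peak matching, FIC and PSM ranking."""

import numpy as np
import pytest

from chima.chem import PROTON_MASS, PeptideForm
from chima.search import (
    FormIndex,
    compute_fic,
    fragment_ions,
    filter_cterm_acyl_forms,
    match_peaks,
    score_and_rank,
    select_candidates,
)
from chima.spectra import Spectrum

from conftest import random_peptide
from oracles import brute_force_fic, oracle_fragment_mzs


def ladder_spectrum(form, scan_id="s", charge=2, keep=None, extra=(), intensity=100.0):
    """Spectrum holding exactly the 1+ b/y ladder (or a subset) of a form."""
    frags = fragment_ions(form, 1)
    peaks = [
        (f.mz, intensity)
        for f in frags
        if keep is None or f.position in keep
    ]
    peaks.extend(extra)
    mz = (form.neutral_mass + charge * PROTON_MASS) / charge
    return Spectrum(scan_id, mz, charge, 10.0, np.array(peaks).reshape(-1, 2))


class TestFragmentIons:
    def test_count_is_2n_minus_2(self):
        frags = fragment_ions(PeptideForm("ACDEFGHIK"), 1)
        assert len(frags) == 16
        assert {f.series for f in frags} == {"b", "y"}

    def test_gk_reference_values(self):
        frags = {(f.series, f.index): f.mz for f in fragment_ions(PeptideForm("GK"), 1)}
        assert frags[("b", 1)] == pytest.approx(58.02874, abs=1e-5)
        assert frags[("y", 1)] == pytest.approx(147.11280, abs=1e-5)

    def test_length_one_peptide_has_no_fragments(self):
        assert fragment_ions(PeptideForm("K"), 2) == []

    def test_mod_deltas_carried_at_positions(self, mods):
        plain = {
            (f.series, f.index): f.mz for f in fragment_ions(PeptideForm("KSTGGKAPR"), 1)
        }
        la = {
            (f.series, f.index): f.mz
            for f in fragment_ions(
                PeptideForm("KSTGGKAPR", mods=((1, mods["la"]),)), 1
            )
        }
        for i in range(1, 9):
            assert la[("b", i)] - plain[("b", i)] == pytest.approx(72.021129, abs=1e-6)
        for i in range(1, 4):
            assert la[("y", i)] == pytest.approx(plain[("y", i)], abs=1e-9)

    def test_complementarity_identity(self, mods, rng):
        """b_i + y_{n-i} neutral masses sum to precursor mass + 2 protons."""
        for _ in range(20):
            seq = random_peptide(rng)
            form = PeptideForm(seq)
            frags = {(f.series, f.index): f.mz for f in fragment_ions(form, 1)}
            n = len(seq)
            total = form.neutral_mass + 2 * PROTON_MASS
            for i in range(1, n):
                assert frags[("b", i)] + frags[("y", n - i)] == pytest.approx(
                    total, abs=1e-9
                )

    def test_against_independent_mass_oracle(self, mods, rng):
        for _ in range(100):
            seq = random_peptide(rng)
            deltas = {}
            mod_assign = []
            k_sites = [i + 1 for i, r in enumerate(seq) if r == "K"]
            if k_sites:
                site = int(rng.choice(k_sites))
                mod_assign = [(site, mods["la"])]
                deltas = {site: mods["la"].delta_mass}
            form = PeptideForm(seq, mods=tuple(mod_assign))
            expected = oracle_fragment_mzs(seq, deltas)
            got = {(f.series, f.index): f.mz for f in fragment_ions(form, 1)}
            for pos, mz in expected.items():
                assert got[pos] == pytest.approx(mz, abs=1e-5)


class TestMatchAndFic:
    def test_complete_ladder_fully_matched(self):
        form = PeptideForm("ACDEFGHIK")
        sp = ladder_spectrum(form)
        matched = match_peaks(sp, fragment_ions(form, 1))
        assert len(matched) == 16
        assert compute_fic(form, sp) == 1.0

    def test_empty_peak_list(self):
        form = PeptideForm("ACDEFGHIK")
        sp = Spectrum("e", 500.0, 2, None, np.empty((0, 2)))
        assert match_peaks(sp, fragment_ions(form, 1)) == {}
        assert compute_fic(form, sp) == 0.0

    def test_half_coverage_boundary(self):
        form = PeptideForm("ACDEFGHIK")
        keep8 = {("b", i) for i in range(1, 5)} | {("y", i) for i in range(1, 5)}
        assert compute_fic(form, ladder_spectrum(form, keep=keep8)) == 0.5
        keep7 = set(list(keep8)[:7])
        assert compute_fic(form, ladder_spectrum(form, keep=keep7)) == pytest.approx(0.4375)

    def test_one_peak_can_match_two_positions(self):
        """No peak exclusivity: one centroid inside two tolerance windows
        counts for both fragment positions."""
        form = PeptideForm("ACDEFGHIK")
        frags = fragment_ions(form, 1)
        b3 = next(f for f in frags if f.position == ("b", 3))
        # a fake companion fragment 20 ppm away on a different position
        collide_mz = b3.mz * (1 + 20e-6)
        fake = [f for f in frags if f.position == ("y", 5)]
        sp = Spectrum(
            "c", 500.0, 2, None, np.array([[b3.mz * (1 + 10e-6), 50.0]])
        )
        doctored = [b3] + [
            type(f)(series="y", index=5, charge=1, mz=collide_mz) for f in fake[:1]
        ]
        matched = match_peaks(sp, doctored, frag_tol_ppm=40)
        assert set(matched) == {("b", 3), ("y", 5)}
        assert matched[("b", 3)].peak_index == matched[("y", 5)].peak_index

    def test_min_rel_intensity_threshold(self):
        form = PeptideForm("ACDEFGHIK")
        frags = fragment_ions(form, 1)
        peaks = [(frags[0].mz, 1.0), (frags[1].mz, 100.0)]
        sp = Spectrum("t", 500.0, 2, None, np.array(peaks))
        matched = match_peaks(sp, frags, min_rel_intensity=0.05)
        assert frags[0].position not in matched
        assert frags[1].position in matched

    def test_fic_invariant_under_intensity_rescaling(self):
        form = PeptideForm("ACDEFGHIK")
        sp = ladder_spectrum(form, keep={("b", 1), ("y", 2), ("y", 7)})
        scaled = Spectrum("s2", sp.precursor_mz, 2, None, sp.peaks * np.array([1.0, 250.0]))
        assert compute_fic(form, sp) == compute_fic(form, scaled)

    def test_fic_monotone_in_added_peaks(self, rng):
        form = PeptideForm("ACDEFGHIKLMNPQR")
        frags = fragment_ions(form, 1)
        order = rng.permutation(len(frags))
        peaks = []
        last = 0.0
        for idx in order:
            peaks.append((frags[idx].mz, 10.0))
            sp = Spectrum("m", 600.0, 2, None, np.array(peaks))
            fic = compute_fic(form, sp)
            assert fic >= last
            last = fic
        assert last == 1.0

    def test_matches_brute_force_all_pairs(self, rng):
        """Engine FIC equals a quadratic all-pairs tolerance scan."""
        for _ in range(100):
            seq = random_peptide(rng)
            form = PeptideForm(seq)
            frags = fragment_ions(form, 1)
            n_peaks = int(rng.integers(3, 40))
            mzs = sorted(
                float(f.mz * (1 + rng.normal(0, 25e-6)))
                for f in rng.choice(frags, size=min(n_peaks, len(frags)))
            ) + sorted(rng.uniform(100, 1500, size=5).tolist())
            sp = Spectrum(
                "r", 700.0, 2, None,
                np.column_stack([sorted(mzs), np.full(len(mzs), 10.0)]),
            )
            fic = compute_fic(form, sp, frag_tol_ppm=40)
            brute = brute_force_fic(
                [(f.series, f.index, f.charge, f.mz) for f in frags],
                sp.mz, 40,
            )
            assert abs(fic - brute) <= 1e-12

    def test_near_isobaric_me3_vs_ac_fragments_distinct(self, mods):
        """Acetyl (+42.01057) and trimethyl (+42.04695) ladders must never be
        merged by the matcher at 40 ppm below m/z 900."""
        ac = PeptideForm("KSTGGKAPR", mods=((1, mods["ac"]),))
        me3 = PeptideForm("KSTGGKAPR", mods=((1, mods["me3"]),))
        ac_frags = fragment_ions(ac, 1)
        me3_frags = [f for f in fragment_ions(me3, 1) if f.mz < 900]
        sp = Spectrum(
            "iso", 500.0, 2, None,
            np.column_stack([[f.mz for f in me3_frags], [10.0] * len(me3_frags)]),
        )
        matched = match_peaks(sp, [f for f in ac_frags if f.mz < 900], frag_tol_ppm=40)
        # b ions carry the mod: none may cross-match the other ladder
        assert not any(series == "b" for series, _ in matched)


class TestCandidateSelection:
    def test_exact_mass_selected(self, mods):
        form = PeptideForm("KSTGGKAPR", mods=((1, mods["la"]),))
        index = FormIndex([form])
        sp = ladder_spectrum(form)
        assert select_candidates(sp, index, 10.0) == [form]

    def test_ppm_window_arithmetic(self):
        form = PeptideForm("ACDEFGHIK")
        mass = form.neutral_mass
        index = FormIndex([form])
        inside = Spectrum("i", (mass * (1 + 9e-6) + 2 * PROTON_MASS) / 2, 2, None, np.empty((0, 2)))
        outside = Spectrum("o", (mass * (1 + 12e-6) + 2 * PROTON_MASS) / 2, 2, None, np.empty((0, 2)))
        assert select_candidates(inside, index, 10.0) == [form]
        assert select_candidates(outside, index, 10.0) == []

    def test_isomers_both_selected(self, isomer_pair):
        a, b = isomer_pair
        index = FormIndex([a, b])
        sp = ladder_spectrum(a)
        assert set(f.key() for f in select_candidates(sp, index, 10.0)) == {
            a.key(),
            b.key(),
        }

    def test_unknown_charge_unions_2_to_4(self):
        form = PeptideForm("ACDEFGHIK")
        index = FormIndex([form])
        mz3 = (form.neutral_mass + 3 * PROTON_MASS) / 3
        sp = Spectrum("u", mz3, 0, None, np.empty((0, 2)))
        assert select_candidates(sp, index, 10.0) == [form]


class TestScoreAndRank:
    def test_single_candidate_delta_is_own_score(self):
        form = PeptideForm("ACDEFGHIK")
        sp = ladder_spectrum(form)
        (psm,) = score_and_rank(sp, [form])
        assert psm.rank_score == pytest.approx(16 + psm.explained_intensity)
        assert psm.delta_score == psm.rank_score

    def test_isomer_tie_retained_for_chimera(self, isomer_pair):
        a, b = isomer_pair
        frags = fragment_ions(a, 1) + fragment_ions(b, 1)
        peaks = sorted({(f.mz, 10.0) for f in frags})
        sp = Spectrum("c", (a.neutral_mass + 2 * PROTON_MASS) / 2, 2, None, np.array(peaks))
        psms = score_and_rank(sp, [a, b])
        assert len(psms) == 2
        # isomers do not shrink each other's delta score
        assert psms[0].delta_score == psms[0].rank_score

    def test_zero_match_candidate_sorted_last(self, mods):
        good = PeptideForm("ACDEFGHIK")
        bad = PeptideForm("WWWWWWWWW")
        sp = ladder_spectrum(good)
        psms = score_and_rank(sp, [bad, good])
        assert psms[0].form.sequence == "ACDEFGHIK"
        assert psms[-1].rank_score == 0.0
        assert psms[-1].delta_score < 0

    def test_deterministic_order(self, isomer_pair):
        a, b = isomer_pair
        sp = ladder_spectrum(a)
        keys1 = [p.form.key() for p in score_and_rank(sp, [a, b])]
        keys2 = [p.form.key() for p in score_and_rank(sp, [b, a])]
        assert keys1 == keys2


class TestCTermAcylFilter:
    def test_internal_acyl_kept_terminal_dropped(self, mods):
        terminal = PeptideForm("STGGK", mods=((5, mods["la"]),), protein_refs=(("P", 1, 5),))
        internal = PeptideForm("KSTGGKAPR", mods=((1, mods["la"]),))
        kept = filter_cterm_acyl_forms([terminal, internal], {"P": 100})
        assert kept == [internal]

    def test_protein_cterm_exemption(self, mods):
        form = PeptideForm("STGGK", mods=((5, mods["la"]),), protein_refs=(("P", 96, 100),))
        assert filter_cterm_acyl_forms([form], {"P": 100}) == [form]
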
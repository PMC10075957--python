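"""Candidate selection, theoretical b/y fragments, peak matching, fragment
ion coverage (FIC) and PSM ranking.

FIC is the identification criterion of this tool: the number of observed b
and y fragment-ion positions divided by the number of theoretical ones,
2(n-1) for a length-n peptide. A position counts as matched if any of its
considered charge states finds a peak within the fragment tolerance; the
denominator never grows with extra charge states, because a position is one
ion. The default tolerances are 10 ppm (precursor) and 40 ppm (fragment).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem import PROTON_MASS, RESIDUE_MASSES, WATER_MASS, PeptideForm
from .spectra import Spectrum

__all__ = [
    "TheoreticalFragment",
    "PeakAssignment",
    "PSM",
    "FormIndex",
    "fragment_ions",
    "select_candidates",
    "match_peaks",
    "compute_fic",
    "score_and_rank",
    "filter_cterm_acyl_forms",
    "DEFAULT_PRECURSOR_TOL_PPM",
    "DEFAULT_FRAGMENT_TOL_PPM",
]

DEFAULT_PRECURSOR_TOL_PPM = 10.0
DEFAULT_FRAGMENT_TOL_PPM = 40.0


@dataclass(frozen=True)
class TheoreticalFragment:
    series: str  # "b" | "y"
    index: int  # 1 .. n-1
    charge: int
    mz: float

    @property
    def position(self) -> tuple:
        return (self.series, self.index)


@dataclass(frozen=True)
class PeakAssignment:
    """The nearest-in-ppm peak recorded for a matched fragment position."""

    peak_index: int
    charge: int
    theoretical_mz: float
    observed_mz: float
    ppm_error: float


def _residue_mod_masses(form: PeptideForm) -> np.ndarray:
    masses = np.array([RESIDUE_MASSES[r] for r in form.sequence])
    for idx, spec in form.mods:
        masses[idx - 1] += spec.delta_mass
    return masses


def fragment_ions(form: PeptideForm, max_frag_charge: int = 1) -> list[TheoreticalFragment]:
    """All b/y fragments at charges 1..max_frag_charge.

    For a length-n peptide there are n-1 positions per series; a length-1
    peptide yields no fragments. Modification deltas are carried at their
    residue positions, so the two ladders of positional isomers differ
    exactly at the site-determining splits.
    """
    n = len(form.sequence)
    if n < 2:
        return []
    masses = _residue_mod_masses(form)
    prefix = np.cumsum(masses)  # b_i neutral = prefix[i-1]
    total = prefix[-1]
    out = []
    for z in range(1, max_frag_charge + 1):
        for i in range(1, n):
            out.append(
                TheoreticalFragment("b", i, z, (prefix[i - 1] + z * PROTON_MASS) / z)
            )
        for i in range(1, n):
            suffix = total - prefix[n - i - 1]
            out.append(
                TheoreticalFragment(
                    "y", i, z, (suffix + WATER_MASS + z * PROTON_MASS) / z
                )
            )
    out.sort(key=lambda f: (f.series, f.charge, f.index))
    return out


class FormIndex:
    """Peptide forms indexed by neutral mass for precursor-window lookup."""

    def __init__(self, forms: Iterable[PeptideForm]):
        decorated = sorted(
            ((f.neutral_mass, f) for f in forms), key=lambda t: (t[0], t[1].key())
        )
        self._masses = [m for m, _ in decorated]
        self._forms = [f for _, f in decorated]

    def __len__(self) -> int:
        return len(self._forms)

    def __iter__(self):
        return iter(self._forms)

    def select(self, neutral_mass: float, tol_ppm: float) -> list[PeptideForm]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = bisect.bisect_left(self._masses, neutral_mass - tol)
        hi = bisect.bisect_right(self._masses, neutral_mass + tol)
        return [
            f
            for m, f in zip(self._masses[lo:hi], self._forms[lo:hi])
            if abs(neutral_mass - m) / m * 1e6 <= tol_ppm
        ]


def select_candidates(
    spectrum: Spectrum,
    index: FormIndex,
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    isotope_error: bool = False,
) -> list[PeptideForm]:
    """Forms whose neutral mass matches the precursor within tolerance.

    An unknown precursor charge (0) falls back to the union over charges
    2-4. With ``isotope_error`` a +1 isotope mis-pick window is also tried.
    """
    charges = [spectrum.precursor_charge] if spectrum.precursor_charge >= 1 else [2, 3, 4]
    seen: dict = {}
    from .chem import ISOTOPE_SPACING

    for z in charges:
        observed = spectrum.precursor_neutral_mass(z)
        targets = [observed] + ([observed - ISOTOPE_SPACING] if isotope_error else [])
        for obs in targets:
            for form in index.select(obs, precursor_tol_ppm):
                seen.setdefault(form.key(), form)
    return list(seen.values())


def match_peaks(
    spectrum: Spectrum,
    fragments: Sequence[TheoreticalFragment],
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    min_rel_intensity: float = 0.0,
) -> dict:
    """Match theoretical fragments to peaks.

    Returns {(series, index): PeakAssignment} keeping, per position, the
    nearest-in-ppm peak over all considered charge states. Peaks are not
    consumed: one peak may match several positions.
    """
    mz = spectrum.mz
    inten = spectrum.intensity
    if len(mz) == 0:
        return {}
    base = spectrum.base_peak_intensity
    min_abs = min_rel_intensity * base
    matched: dict = {}
    for frag in fragments:
        tol = frag.mz * frag_tol_ppm * 1e-6
        lo = np.searchsorted(mz, frag.mz - tol, side="left")
        hi = np.searchsorted(mz, frag.mz + tol, side="right")
        best: Optional[PeakAssignment] = None
        for j in range(lo, hi):
            if inten[j] < min_abs:
                continue
            ppm = (mz[j] - frag.mz) / frag.mz * 1e6
            if best is None or abs(ppm) < abs(best.ppm_error):
                best = PeakAssignment(
                    peak_index=int(j),
                    charge=frag.charge,
                    theoretical_mz=frag.mz,
                    observed_mz=float(mz[j]),
                    ppm_error=float(ppm),
                )
        if best is not None:
            prev = matched.get(frag.position)
            if prev is None or abs(best.ppm_error) < abs(prev.ppm_error):
                matched[frag.position] = best
    return matched


def compute_fic(
    form: PeptideForm,
    spectrum: Spectrum,
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    max_frag_charge: int = 1,
    min_rel_intensity: float = 0.0,
) -> float:
    """Fragment ion coverage: matched positions / 2(n-1)."""
    n = len(form.sequence)
    if n < 2:
        return 0.0
    frags = fragment_ions(form, max_frag_charge)
    matched = match_peaks(spectrum, frags, frag_tol_ppm, min_rel_intensity)
    return len(matched) / (2 * (n - 1))


@dataclass
class PSM:
    """A spectrum / peptide-form pairing with its match evidence."""

    scan_id: str
    form: PeptideForm
    charge: int
    precursor_mz: float
    retention_time: Optional[float]
    matched_positions: frozenset
    assignments: dict
    fic: float
    n_matched_ions: int
    explained_intensity: float
    rank_score: float
    delta_score: float
    precursor_error_ppm: float
    is_decoy: bool
    confidence_class: str = "unclassified"
    chimera_member: bool = False
    site_ambiguous: bool = False

    @property
    def sequence(self) -> str:
        return self.form.sequence

    def key(self) -> tuple:
        return self.form.key()


def _build_psm(
    spectrum: Spectrum,
    form: PeptideForm,
    charge: int,
    frag_tol_ppm: float,
    max_frag_charge: int,
    min_rel_intensity: float,
) -> PSM:
    frags = fragment_ions(form, max_frag_charge)
    assignments = match_peaks(spectrum, frags, frag_tol_ppm, min_rel_intensity)
    n = len(form.sequence)
    denom = 2 * (n - 1) if n >= 2 else 1
    fic = len(assignments) / denom
    total = float(spectrum.intensity.sum()) if len(spectrum.peaks) else 0.0
    peak_ids = {a.peak_index for a in assignments.values()}
    explained = (
        float(spectrum.intensity[sorted(peak_ids)].sum()) / total if total > 0 else 0.0
    )
    mass = form.neutral_mass
    observed = spectrum.precursor_neutral_mass(charge)
    return PSM(
        scan_id=spectrum.scan_id,
        form=form,
        charge=charge,
        precursor_mz=spectrum.precursor_mz,
        retention_time=spectrum.retention_time,
        matched_positions=frozenset(assignments),
        assignments=assignments,
        fic=fic,
        n_matched_ions=len(assignments),
        explained_intensity=explained,
        rank_score=len(assignments) + explained,
        delta_score=0.0,
        precursor_error_ppm=(observed - mass) / mass * 1e6,
        is_decoy=form.is_decoy,
    )


def score_and_rank(
    spectrum: Spectrum,
    candidates: Sequence[PeptideForm],
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    max_frag_charge: Optional[int] = None,
    min_rel_intensity: float = 0.0,
) -> list[PSM]:
    """Score every candidate against the spectrum and rank deterministically.

    rank_score = matched ion count + explained intensity fraction; ties are
    broken by explained intensity, then by the lexicographic form key.
    delta_score of a PSM is the gap to the best-scoring candidate that is
    NOT a positional isomer of it (isomers are kept close on purpose, for
    chimera dissection); with no such competitor it equals the PSM's own
    score.
    """
    charge = spectrum.precursor_charge if spectrum.precursor_charge >= 1 else 2
    if max_frag_charge is None:
        max_frag_charge = max(1, min(charge - 1, 2))
    psms = [
        _build_psm(spectrum, f, charge, frag_tol_ppm, max_frag_charge, min_rel_intensity)
        for f in candidates
    ]
    psms.sort(key=lambda p: (-p.rank_score, -p.explained_intensity, p.form.key()))
    for psm in psms:
        rivals = [
            q.rank_score
            for q in psms
            if q is not psm and not q.form.is_isomer_of(psm.form)
        ]
        psm.delta_score = psm.rank_score - max(rivals) if rivals else psm.rank_score
    return psms


_ACYL_MODS = frozenset({"ac", "la", "cr", "hib", "bz"})


def filter_cterm_acyl_forms(
    forms: Iterable[PeptideForm],
    protein_lengths: Optional[dict] = None,
    acyl_mods: frozenset = _ACYL_MODS,
) -> list[PeptideForm]:
    """Drop forms ending in an acylated K, unless at the protein C-terminus.

    Trypsin does not cleave after an acylated lysine, so a peptide whose
    C-terminal K carries an acyl mark cannot be a genuine tryptic product
    except at the protein C-terminus. Pass ``protein_lengths`` (protein id
    -> sequence length) to enable the C-terminal exemption.
    """
    kept = []
    for form in forms:
        last = len(form.sequence)
        mod = form.mods_by_index.get(last)
        if mod is not None and form.sequence[-1] == "K" and mod.name in acyl_mods:
            at_cterm = protein_lengths is not None and any(
                protein_lengths.get(pid) == end for pid, _, end in form.protein_refs
            )
            if not at_cterm:
                continue
        kept.append(form)
    return kept
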
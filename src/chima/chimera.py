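"""Dissection of chimeric spectra from coeluted positional-isomer peptides.

Two peptides with the same sequence and the same modification multiset but
different site assignments co-isolate at the same precursor m/z and coelute
closely; their mixed MS/MS spectrum looks like a poor match to either form
alone. Here each isomer is scored against the full spectrum: a member is
accepted as a co-identification when its fragment ion coverage passes the
cutoff AND at least one of its site-determining ions — fragments whose m/z
matches nothing in any other member's theoretical ladder — is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem import ChimaError, PeptideForm
from .search import (
    DEFAULT_FRAGMENT_TOL_PPM,
    PSM,
    fragment_ions,
    match_peaks,
    score_and_rank,
)
from .spectra import Spectrum

__all__ = ["ChimeraGroup", "site_determining_ions", "dissect_chimera"]


class NonIsomericError(ChimaError):
    """Chimera operations require members with identical sequence and mod multiset."""


@dataclass
class ChimeraGroup:
    """A spectrum paired with >=2 isomeric candidate forms."""

    scan_id: str
    members: list  # PeptideForm
    psms: list  # PSM per member, same order
    unique_matched: dict  # form key -> set of matched unique positions
    unique_total: dict  # form key -> set of all unique positions
    shared_positions: set
    accepted: list  # accepted PSMs
    ambiguous: bool  # peptide-level evidence without site localization
    combined_explained_intensity: float = 0.0


def _require_isomers(forms: Sequence[PeptideForm]) -> None:
    first = forms[0]
    for other in forms[1:]:
        if not first.is_isomer_of(other):
            raise NonIsomericError(
                f"{first.annotated()} and {other.annotated()} are not "
                "positional isomers"
            )


def _ppm_close(a: float, b: float, tol_ppm: float) -> bool:
    return abs(a - b) / b * 1e6 <= tol_ppm


def _unique_positions(
    form: PeptideForm,
    others: Sequence[PeptideForm],
    frag_tol_ppm: float,
) -> set:
    """Positions of ``form`` whose 1+ m/z matches nothing in any other ladder."""
    own = [f for f in fragment_ions(form, 1)]
    other_mz = [
        frag.mz for other in others for frag in fragment_ions(other, 1)
    ]
    unique = set()
    for frag in own:
        if not any(_ppm_close(frag.mz, mz, frag_tol_ppm) for mz in other_mz):
            unique.add(frag.position)
    return unique


def site_determining_ions(
    form_a: PeptideForm,
    form_b: PeptideForm,
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> tuple:
    """Partition fragment positions into (unique-to-A, unique-to-B, shared).

    Comparison is on singly charged theoretical m/z at the fragment
    tolerance; the operation is symmetric in its arguments. Shared
    positions are reported once (they are the same splits in both ladders).
    """
    _require_isomers([form_a, form_b])
    unique_a = _unique_positions(form_a, [form_b], frag_tol_ppm)
    unique_b = _unique_positions(form_b, [form_a], frag_tol_ppm)
    all_positions = {f.position for f in fragment_ions(form_a, 1)}
    shared = all_positions - unique_a - unique_b
    return unique_a, unique_b, shared


def dissect_chimera(
    spectrum: Spectrum,
    members: Sequence[PeptideForm],
    fic_cutoff: float = 0.5,
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    max_frag_charge: int = 1,
    min_rel_intensity: float = 0.0,
) -> ChimeraGroup:
    """Score each isomer against the full spectrum and accept co-identifications.

    A member is accepted iff (a) its own FIC >= ``fic_cutoff`` and (b) at
    least one of its site-determining ions is matched. If no member has a
    matched unique ion the group is flagged ambiguous: the peptide and its
    modification multiset are supported, but no site assignment is. If
    exactly one member satisfies (b) the group collapses to that single PSM.
    """
    if len(members) < 2:
        raise ValueError("a chimera group needs at least two members")
    _require_isomers(members)
    psms = score_and_rank(
        spectrum,
        list(members),
        frag_tol_ppm=frag_tol_ppm,
        max_frag_charge=max_frag_charge,
        min_rel_intensity=min_rel_intensity,
    )
    forms = [p.form for p in psms]
    unique_total: dict = {}
    unique_matched: dict = {}
    for i, psm in enumerate(psms):
        others = [f for j, f in enumerate(forms) if j != i]
        uniq = _unique_positions(psm.form, others, frag_tol_ppm)
        unique_total[psm.form.key()] = uniq
        unique_matched[psm.form.key()] = uniq & set(psm.matched_positions)
    all_positions = {f.position for f in fragment_ions(forms[0], 1)}
    shared = all_positions - set().union(*unique_total.values())

    accepted = [
        psm
        for psm in psms
        if psm.fic >= fic_cutoff and unique_matched[psm.form.key()]
    ]
    ambiguous = not any(unique_matched[p.form.key()] for p in psms)
    for psm in accepted:
        psm.chimera_member = len(accepted) >= 2
    if ambiguous:
        for psm in psms:
            psm.site_ambiguous = True
    peak_ids = set()
    for psm in psms:
        peak_ids.update(a.peak_index for a in psm.assignments.values())
    total = float(spectrum.intensity.sum()) if len(spectrum.peaks) else 0.0
    combined = (
        float(spectrum.intensity[sorted(peak_ids)].sum()) / total if total else 0.0
    )
    return ChimeraGroup(
        scan_id=spectrum.scan_id,
        members=forms,
        psms=psms,
        unique_matched=unique_matched,
        unique_total=unique_total,
        shared_positions=shared,
        accepted=accepted,
        ambiguous=ambiguous,
        combined_explained_intensity=combined,
    )
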
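"""Site-level reporting in mature histone numbering, and coexistence summaries.

Histone sites are conventionally numbered after removal of the initiator
methionine (H3K9, H2AK9la, ...), so for M-initiated proteins the mature
position is the full-sequence position minus one. Full coordinates are
retained alongside for traceability.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .chem import ChimaError
from .proteolysis import ProteinRecord
from .search import PSM

__all__ = ["SiteRecord", "CoexistenceRecord", "map_sites", "summarize_coexistence"]


class CoordinateError(ChimaError):
    """A PSM's protein coordinates disagree with the protein sequence."""


@dataclass
class SiteRecord:
    protein_id: str
    residue: str
    mature_position: int
    full_position: int
    modification: str
    psm_count: int
    best_fic: float
    confidence_class: str  # best over supporting PSMs
    shared_evidence: bool  # peptide maps to more than one protein

    @property
    def label(self) -> str:
        """Field-style site name, e.g. ``K9la``."""
        return f"{self.residue}{self.mature_position}{self.modification}"


@dataclass
class CoexistenceRecord:
    form_key: tuple
    sites: tuple  # ((protein id, mature position, mod name), ...)
    psm_count: int


_CONFIDENCE_ORDER = {"high": 0, "moderate": 1, "unclassified": 2, "rejected": 3}


def map_sites(
    psms: Sequence[PSM],
    proteins: Mapping[str, ProteinRecord],
) -> list[SiteRecord]:
    """Aggregate accepted PSMs into one record per (protein, site, mod).

    Peptides with several protein references yield a record per protein,
    flagged as shared evidence. Input order does not affect the result.
    """
    buckets: dict = {}
    for psm in psms:
        form = psm.form
        shared = len(form.protein_refs) > 1
        for protein_id, start, end in form.protein_refs:
            protein = proteins[protein_id]
            if protein.sequence[start - 1 : end] != form.sequence:
                raise CoordinateError(
                    f"{form.sequence!r} does not match {protein_id} "
                    f"positions {start}-{end}"
                )
            met_offset = 1 if protein.sequence.startswith("M") else 0
            for idx, spec in form.mods:
                full_pos = start + idx - 1
                residue = protein.sequence[full_pos - 1]
                key = (protein_id, full_pos, spec.name)
                rec = buckets.get(key)
                if rec is None:
                    buckets[key] = SiteRecord(
                        protein_id=protein_id,
                        residue=residue,
                        mature_position=full_pos - met_offset,
                        full_position=full_pos,
                        modification=spec.name,
                        psm_count=1,
                        best_fic=psm.fic,
                        confidence_class=psm.confidence_class,
                        shared_evidence=shared,
                    )
                else:
                    rec.psm_count += 1
                    rec.best_fic = max(rec.best_fic, psm.fic)
                    if (
                        _CONFIDENCE_ORDER.get(psm.confidence_class, 2)
                        < _CONFIDENCE_ORDER.get(rec.confidence_class, 2)
                    ):
                        rec.confidence_class = psm.confidence_class
                    rec.shared_evidence = rec.shared_evidence or shared
    return [buckets[k] for k in sorted(buckets)]


def summarize_coexistence(
    psms: Sequence[PSM],
    target_mods: Iterable[str] = ("la",),
) -> tuple:
    """Coexistence records plus a histogram of background-mod co-occurrence.

    The histogram counts, per background modification name, the number of
    distinct accepted peptide forms on which it co-occurs with the target
    PTM. Records are emitted for every multiply modified peptide form.
    """
    target_mods = set(target_mods)
    by_form: dict = defaultdict(int)
    form_obj: dict = {}
    for psm in psms:
        by_form[psm.form.key()] += 1
        form_obj[psm.form.key()] = psm.form
    records = []
    histogram: dict = defaultdict(int)
    for key in sorted(by_form):
        form = form_obj[key]
        if len(form.mods) < 2:
            continue
        sites = []
        for idx, spec in form.mods:
            if form.protein_refs:
                pid, start, _ = form.protein_refs[0]
                # mature numbering needs the protein; reported downstream.
                sites.append((pid, start + idx - 1, spec.name))
            else:
                sites.append(("", idx, spec.name))
        records.append(
            CoexistenceRecord(form_key=key, sites=tuple(sites), psm_count=by_form[key])
        )
        names = [spec.name for _, spec in form.mods]
        if any(n in target_mods for n in names):
            for n in set(names) - target_mods:
                histogram[n] += 1
    return records, dict(histogram)


def sites_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "site": r.label,
                "residue": r.residue,
                "mature_position": r.mature_position,
                "full_position": r.full_position,
                "modification": r.modification,
                "psm_count": r.psm_count,
                "best_fic": r.best_fic,
                "confidence_class": r.confidence_class,
                "shared_evidence": r.shared_evidence,
            }
            for r in records
        ]
    )
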
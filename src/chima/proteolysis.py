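"""FASTA reading, reversed-decoy construction, and in-silico digestion.

Decoys are exact sequence reversals appended after the targets, giving the
reverse-concatenated database used for target-decoy FDR estimation. The
default enzyme is trypsin (cleave after K/R, blocked by a following P) with
generous missed cleavages: histone tails are K/R-rich and acylation
suppresses cleavage in vitro, so real histone peptides carry many internal
K/R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from Bio import SeqIO

from .chem import ChimaError

__all__ = [
    "ProteinRecord",
    "PeptideCandidate",
    "Enzyme",
    "TRYPSIN",
    "FastaFormatError",
    "load_fasta",
    "bundled_histones",
    "make_decoys",
    "digest",
    "digest_database",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "rev_"


class FastaFormatError(ChimaError):
    """Malformed or empty FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str
    is_decoy: bool = False


@dataclass(frozen=True)
class PeptideCandidate:
    """A digestion product with 1-based inclusive protein coordinates."""

    sequence: str
    protein_id: str
    start: int
    end: int
    missed_cleavages: int
    is_decoy: bool = False


@dataclass(frozen=True)
class Enzyme:
    """Cleavage rule: cut after ``cleave_after`` unless followed by ``blocked_by``."""

    name: str
    cleave_after: frozenset
    blocked_by: frozenset = frozenset()

    def cleavage_sites(self, sequence: str) -> list[int]:
        """0-based indices i such that the bond after sequence[i] is cut."""
        sites = []
        for i in range(len(sequence) - 1):
            if sequence[i] in self.cleave_after and sequence[i + 1] not in self.blocked_by:
                sites.append(i)
        return sites


TRYPSIN = Enzyme("trypsin", frozenset("KR"), frozenset("P"))


def load_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, in file order.

    Sequences are uppercased and '*' stop characters stripped. An empty file
    or a record without sequence raises :class:`FastaFormatError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has no sequence")
        records.append(
            ProteinRecord(id=rec.id, description=rec.description, sequence=seq)
        )
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def bundled_histones() -> list[ProteinRecord]:
    """The small human core-histone FASTA shipped for examples and simulation."""
    with resources.as_file(
        resources.files("chima.data").joinpath("histones.fasta")
    ) as p:
        return load_fasta(p)


def make_decoys(proteins: Iterable[ProteinRecord], prefix: str = DECOY_PREFIX) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, flagged and id-prefixed."""
    return [
        ProteinRecord(
            id=prefix + p.id,
            description=f"decoy of {p.id}",
            sequence=p.sequence[::-1],
            is_decoy=True,
        )
        for p in proteins
    ]


def digest(
    protein: ProteinRecord,
    enzyme: Enzyme = TRYPSIN,
    max_missed: int = 4,
    length_range: tuple = (5, 35),
) -> list[PeptideCandidate]:
    """All fully enzymatic peptides with up to ``max_missed`` internal sites.

    Coordinates are 1-based inclusive into the protein; output is ordered by
    start position then peptide length.
    """
    min_len, max_len = length_range
    if min_len > max_len:
        raise ValueError(f"length range inverted: {length_range}")
    seq = protein.sequence
    # Fragment boundaries: starts after each cleavage site, plus termini.
    cut_after = enzyme.cleavage_sites(seq)
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i for i in cut_after] + [len(seq) - 1]  # 0-based last residue
    out = []
    for si, s in enumerate(starts):
        for missed in range(0, max_missed + 1):
            ei = si + missed
            if ei >= len(ends):
                break
            e = ends[ei]
            length = e - s + 1
            if length < min_len or length > max_len:
                continue
            out.append(
                PeptideCandidate(
                    sequence=seq[s : e + 1],
                    protein_id=protein.id,
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=missed,
                    is_decoy=protein.is_decoy,
                )
            )
    out.sort(key=lambda c: (c.start, c.end - c.start))
    return out


def digest_database(
    proteins: Iterable[ProteinRecord],
    enzyme: Enzyme = TRYPSIN,
    max_missed: int = 4,
    length_range: tuple = (5, 35),
    met_clip: bool = True,
) -> list[PeptideCandidate]:
    """Digest a protein list, including initiator-Met-clipped variants.

    When a protein starts with M and ``met_clip`` is on, the Met-removed
    sequence is digested as well; its peptides keep full-sequence
    coordinates, and duplicates are collapsed.
    """
    seen: dict = {}
    for protein in proteins:
        for cand in digest(protein, enzyme, max_missed, length_range):
            seen.setdefault((cand.protein_id, cand.start, cand.end), cand)
        if met_clip and protein.sequence.startswith("M") and len(protein.sequence) > 1:
            clipped = ProteinRecord(
                id=protein.id,
                description=protein.description,
                sequence=protein.sequence[1:],
                is_decoy=protein.is_decoy,
            )
            for cand in digest(clipped, enzyme, max_missed, length_range):
                shifted = PeptideCandidate(
                    sequence=cand.sequence,
                    protein_id=cand.protein_id,
                    start=cand.start + 1,
                    end=cand.end + 1,
                    missed_cleavages=cand.missed_cleavages,
                    is_decoy=cand.is_decoy,
                )
                seen.setdefault((shifted.protein_id, shifted.start, shifted.end), shifted)
    return list(seen.values())
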
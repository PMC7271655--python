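"""Peptide-to-protein site mapping and ambiguity accounting.

Localized modifications map directly to protein coordinates.  Unlocalized
glycans follow the counting convention used for glycopeptide site tables:
when a peptide carries ``g`` unlocalized glycans and exactly ``g`` candidate
Ser/Thr residues, each candidate is a forced, unambiguous site; when the
candidates outnumber the glycans, one ambiguous site group is emitted whose
alternative positions are displayed semicolon-joined (e.g. ``"402;403"``).
"""

from __future__ import annotations

import logging

from .errors import AmbiguousLocationError, InconsistencyError, MappingError
from .model import (
    GLYCO_RESIDUES,
    PHOSPHO_RESIDUES,
    ProteinEntry,
    QuantifiedPeptide,
    SiteCall,
)
from .model import site_key  # re-exported: canonical key for set operations

__all__ = [
    "locate_peptide",
    "assign_sites",
    "classify_multiplicity",
    "site_key",
    "map_records",
]

logger = logging.getLogger(__name__)


def locate_peptide(peptide: str, protein: ProteinEntry) -> list[int]:
    """All (possibly overlapping) 1-based start positions of ``peptide`` in
    the protein, in order; empty list when absent."""
    if not peptide:
        return []
    starts = []
    idx = protein.sequence.find(peptide)
    while idx >= 0:
        starts.append(idx + 1)
        idx = protein.sequence.find(peptide, idx + 1)
    return starts


def classify_multiplicity(record: QuantifiedPeptide) -> str:
    """``single`` iff the peptide carries exactly one glycan (localized or
    not); ``multiple`` otherwise."""
    n = len(record.glyco_mods)
    if n == 0:
        raise InconsistencyError(
            f"{record.peptide}: no glycan modifications on a glyco record"
        )
    return "single" if n == 1 else "multiple"


def _resolve_start(record: QuantifiedPeptide, protein: ProteinEntry) -> int:
    starts = locate_peptide(record.peptide, protein)
    if not starts:
        raise MappingError(
            f"peptide {record.peptide} not found in {protein.accession}"
        )
    if len(starts) > 1:
        raise AmbiguousLocationError(
            f"peptide {record.peptide} occurs at starts {starts} in "
            f"{protein.accession}"
        )
    if record.start is not None and record.start != starts[0]:
        raise MappingError(
            f"peptide {record.peptide}: declared start {record.start} "
            f"disagrees with located start {starts[0]}"
        )
    return starts[0]


def assign_sites(
    record: QuantifiedPeptide, protein: ProteinEntry
) -> list[SiteCall]:
    """Map a modified peptide onto its protein and emit site calls."""
    start = _resolve_start(record, protein)
    glyco = bool(record.glyco_mods)
    phospho = bool(record.phospho_mods)
    calls: list[SiteCall] = []
    if glyco:
        calls.extend(_assign_kind(record, protein, start, glyco=True))
    if phospho:
        calls.extend(_assign_kind(record, protein, start, glyco=False))
    return calls


def _assign_kind(
    record: QuantifiedPeptide,
    protein: ProteinEntry,
    start: int,
    glyco: bool,
) -> list[SiteCall]:
    mods = record.glyco_mods if glyco else record.phospho_mods
    residues = GLYCO_RESIDUES if glyco else PHOSPHO_RESIDUES
    kind = "glyco" if glyco else "phospho"
    multiplicity = (
        classify_multiplicity(record) if glyco else "single"
    )
    localized = [m for m in mods if m.localized]
    n_unlocalized = len(mods) - len(localized)
    calls: list[SiteCall] = []
    for mod in localized:
        pos = start + mod.position - 1
        if protein.sequence[pos - 1] not in residues:
            raise InconsistencyError(
                f"{record.peptide}: {mod.kind}@{mod.position} maps to "
                f"{protein.sequence[pos - 1]}{pos}, not one of {sorted(residues)}"
            )
        calls.append(
            SiteCall(
                accession=protein.accession,
                positions=(pos,),
                kind=kind,
                multiplicity=multiplicity,
                peptides=(record.peptide,),
            )
        )
    if n_unlocalized:
        taken = {m.position for m in localized}
        candidates = tuple(
            start + i
            for i, aa in enumerate(record.peptide)
            if aa in residues and (i + 1) not in taken
        )
        if n_unlocalized > len(candidates):
            raise InconsistencyError(
                f"{record.peptide}: {n_unlocalized} unlocalized {kind} "
                f"modifications but only {len(candidates)} candidate residues"
            )
        if n_unlocalized == len(candidates):
            # forced: each candidate must carry one modification
            for pos in candidates:
                calls.append(
                    SiteCall(
                        accession=protein.accession,
                        positions=(pos,),
                        kind=kind,
                        multiplicity=multiplicity,
                        peptides=(record.peptide,),
                    )
                )
        else:
            calls.append(
                SiteCall(
                    accession=protein.accession,
                    positions=candidates,
                    kind=kind,
                    multiplicity=multiplicity,
                    peptides=(record.peptide,),
                )
            )
    return calls


def map_records(
    records: list[QuantifiedPeptide],
    proteome: list[ProteinEntry],
) -> tuple[list[tuple[QuantifiedPeptide, list[SiteCall]]], dict[str, int]]:
    """Map every record; skip (with a logged warning and a counter) records
    whose peptide is missing, multiply placed, or on an unknown protein."""
    by_accession = {p.accession: p for p in proteome}
    mapped: list[tuple[QuantifiedPeptide, list[SiteCall]]] = []
    skipped = {"unknown_protein": 0, "unmapped": 0, "ambiguous_location": 0}
    for record in records:
        protein = by_accession.get(record.accession)
        if protein is None:
            skipped["unknown_protein"] += 1
            logger.warning("unknown protein %s", record.accession)
            continue
        try:
            calls = assign_sites(record, protein)
        except AmbiguousLocationError as exc:
            skipped["ambiguous_location"] += 1
            logger.warning("%s", exc)
            continue
        except MappingError as exc:
            skipped["unmapped"] += 1
            logger.warning("%s", exc)
            continue
        mapped.append((record, calls))
    return mapped, skipped
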
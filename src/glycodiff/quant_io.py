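"""Reading/writing FASTA and quantification tables; channel normalization
and ratio computation.

Quant-table schema (TSV, UTF-8, '.' decimal): columns ``peptide``,
``accession``, ``start`` (optional, may be empty), ``mods``
(semicolon-joined ``KIND@pos`` or ``KIND@?xN`` for N unlocalized), then one
column per declared channel label.  Missing channel values are empty cells;
contrasts touching them are dropped for that record, never set to zero.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .designs import SimulationDesign
from .errors import NormalizationError, ParseError
from .model import (
    AMINO_ACIDS,
    Modification,
    ProteinEntry,
    QuantifiedPeptide,
    RatioRow,
    SyntheticTruth,
    TruthEntry,
)

WT_CONTRAST = "WT2/WT1"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA; header token before first whitespace becomes
    the accession, sequence lines are concatenated and uppercased."""
    path = Path(path)
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    for rec in records:
        accession = rec.id
        if accession in seen:
            raise ParseError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        sequence = str(rec.seq).upper()
        bad = set(sequence) - set(AMINO_ACIDS)
        if bad:
            raise ParseError(
                f"{path}: record {accession!r} has illegal residue(s) "
                f"{sorted(bad)}"
            )
        entries.append(
            ProteinEntry(accession, sequence, rec.description[len(rec.id):].strip())
        )
    return entries


def write_fasta(entries: list[ProteinEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.description)
        for e in entries
    ]
    with open(path, "w", encoding="utf-8") as handle:
        SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------------------
# Modification strings

def format_mods(mods: tuple[Modification, ...]) -> str:
    """Serialize modifications: localized as ``KIND@pos`` in order,
    unlocalized collapsed to ``KIND@?xN`` per kind."""
    parts: list[str] = []
    unlocalized: dict[str, int] = {}
    for mod in mods:
        if mod.localized:
            parts.append(f"{mod.kind}@{mod.position}")
        else:
            unlocalized[mod.kind] = unlocalized.get(mod.kind, 0) + 1
    for kind in sorted(unlocalized):
        parts.append(f"{kind}@?x{unlocalized[kind]}")
    return ";".join(parts)


def parse_mods(text: str) -> tuple[Modification, ...]:
    mods: list[Modification] = []
    if not text.strip():
        return ()
    for token in text.split(";"):
        token = token.strip()
        if "@" not in token:
            raise ParseError(f"malformed modification {token!r}")
        kind, _, loc = token.partition("@")
        if loc.startswith("?"):
            count_text = loc[1:]
            count = 1
            if count_text:
                if not count_text.startswith("x"):
                    raise ParseError(f"malformed modification {token!r}")
                count = int(count_text[1:])
            mods.extend(Modification(kind, None) for _ in range(count))
        else:
            try:
                mods.append(Modification(kind, int(loc)))
            except ValueError as exc:
                raise ParseError(f"malformed modification {token!r}") from exc
    return tuple(mods)


# ---------------------------------------------------------------------------
# Quant tables

def _format_value(value: float | None) -> str:
    # repr gives the shortest string that round-trips the float exactly
    if value is None:
        return ""
    return repr(float(value))


def write_quant_table(
    records: list[QuantifiedPeptide], design: SimulationDesign, path: str | Path
) -> None:
    labels = design.channel_labels
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(["peptide", "accession", "start", "mods", *labels]))
        handle.write("\n")
        for rec in records:
            row = [
                rec.peptide,
                rec.accession,
                "" if rec.start is None else str(rec.start),
                format_mods(rec.modifications),
            ]
            row.extend(_format_value(rec.channel_values.get(l)) for l in labels)
            handle.write("\t".join(row))
            handle.write("\n")


def read_quant_table(
    path: str | Path, design: SimulationDesign
) -> list[QuantifiedPeptide]:
    """Read a quant TSV.  Row-level problems are collected and reported
    together (with 1-based row numbers) in a single :class:`ParseError`."""
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["peptide", "accession", "start", "mods", *design.channel_labels]
        if header != expected:
            raise ParseError(
                f"{path}: header {header!r} does not match declared schema "
                f"{expected!r}"
            )
        records: list[QuantifiedPeptide] = []
        problems: list[str] = []
        for row_no, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(expected):
                problems.append(f"row {row_no}: {len(fields)} fields")
                continue
            peptide, accession, start_text, mods_text = fields[:4]
            try:
                mods = parse_mods(mods_text)
                values: dict[str, float | None] = {}
                for label, text in zip(design.channel_labels, fields[4:]):
                    if not text.strip():
                        values[label] = None
                        continue
                    value = float(text)
                    if value < 0:
                        raise ParseError(f"negative abundance in {label}")
                    values[label] = value
                records.append(
                    QuantifiedPeptide(
                        peptide=peptide,
                        accession=accession,
                        start=int(start_text) if start_text.strip() else None,
                        modifications=mods,
                        channel_values=values,
                        source_method=design.source_method,
                    )
                )
            except (ParseError, ValueError) as exc:
                problems.append(f"row {row_no}: {exc}")
        if problems:
            raise ParseError(f"{path}: " + "; ".join(problems))
    return records


# ---------------------------------------------------------------------------
# Truth registry

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "accession\tposition\tisoform\teffect_ratio\tmultiplicity"
            "\tpeptide\tpeptide_start\n"
        )
        for e in truth.entries:
            handle.write(
                f"{e.accession}\t{e.position}\t{e.isoform}\t"
                f"{e.effect_ratio!r}\t{e.multiplicity}\t"
                f"{e.peptide}\t{e.peptide_start}\n"
            )


def read_truth(path: str | Path) -> SyntheticTruth:
    entries = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("accession\t"):
            raise ParseError(f"{path}: not a truth registry")
        for line in handle:
            acc, pos, iso, ratio, mult, pep, pstart = line.rstrip("\n").split("\t")
            entries.append(
                TruthEntry(acc, int(pos), iso, float(ratio), mult, pep, int(pstart))
            )
    return SyntheticTruth(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Normalization

def normalize_channels(
    records: list[QuantifiedPeptide], method: str = "median_center"
) -> list[QuantifiedPeptide]:
    """Median-center channels on the log10 scale.

    Each channel is rescaled so its median log10 abundance equals the mean
    of the per-channel medians; ``"none"`` is the identity.  Idempotent.
    """
    if method == "none":
        return records
    if method != "median_center":
        raise ValueError(f"unknown normalization method {method!r}")
    labels: list[str] = []
    for rec in records:
        for label in rec.channel_values:
            if label not in labels:
                labels.append(label)
    medians: dict[str, float] = {}
    for label in labels:
        values = [
            rec.channel_values[label]
            for rec in records
            if rec.channel_values.get(label) not in (None, 0.0)
        ]
        if not values:
            raise NormalizationError(f"channel {label!r} has no usable values")
        medians[label] = float(np.median(np.log10(values)))
    target = float(np.mean(list(medians.values())))
    out = []
    for rec in records:
        scaled = {
            label: (
                None
                if value is None
                else value * 10.0 ** (target - medians[label])
            )
            for label, value in rec.channel_values.items()
        }
        out.append(
            QuantifiedPeptide(
                peptide=rec.peptide,
                accession=rec.accession,
                start=rec.start,
                modifications=rec.modifications,
                channel_values=scaled,
                source_method=rec.source_method,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ratios

def _usable(value: float | None) -> bool:
    return value is not None and value > 0 and math.isfinite(value)


def compute_ratios(record: QuantifiedPeptide, design: SimulationDesign) -> RatioRow:
    """Contrast ratios for one record.

    glyco_tmt10: one KO-clone/WT ratio per KO channel.  phospho_tmt: KO
    ratios against the mean of the two WT channels, plus the WT2/WT1
    contrast.  dimethyl: one medium/light (KO/WT) ratio.  Contrasts with a
    missing numerator are absent; contrasts with an unusable denominator are
    listed in ``undefined``.
    """
    values = record.channel_values
    ratios: dict[str, float] = {}
    undefined: list[str] = []

    def emit(name: str, numerator: float | None, denominator: float | None) -> None:
        if denominator is None or not _usable(denominator):
            undefined.append(name)
            return
        if numerator is None:
            return  # absent, not zero
        ratios[name] = numerator / denominator

    if design.kind == "phospho_tmt":
        wt1, wt2 = (values.get(c.label) for c in design.wt_channels)
        wt_mean = (
            (wt1 + wt2) / 2.0 if _usable(wt1) and _usable(wt2) else None
        )
        for chan in design.ko_channels:
            emit(design.contrast_label(chan), values.get(chan.label), wt_mean)
        emit(WT_CONTRAST, wt2, wt1)
    else:
        wt = values.get("WT")
        for chan in design.ko_channels:
            emit(design.contrast_label(chan), values.get(chan.label), wt)
    log10_ratios = {k: math.log10(v) for k, v in ratios.items() if v > 0}
    # a zero numerator yields ratio 0, which has no log; treat as undefined
    for name, value in list(ratios.items()):
        if value <= 0:
            del ratios[name]
            undefined.append(name)
    return RatioRow(
        record=record,
        ratios=ratios,
        log10_ratios=log10_ratios,
        undefined=tuple(undefined),
    )


def compute_ratio_rows(
    records: list[QuantifiedPeptide], design: SimulationDesign
) -> list[RatioRow]:
    return [compute_ratios(rec, design) for rec in records]


def write_ratio_table(
    rows: list[RatioRow], design: SimulationDesign, path: str | Path
) -> None:
    contrasts = [design.contrast_label(c) for c in design.ko_channels]
    if design.kind == "phospho_tmt":
        contrasts.append(WT_CONTRAST)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(["peptide", "accession", "mods", *contrasts]))
        handle.write("\n")
        for row in rows:
            out = [
                row.record.peptide,
                row.record.accession,
                format_mods(row.record.modifications),
            ]
            out.extend(
                _format_value(row.ratios.get(c)) for c in contrasts
            )
            handle.write("\t".join(out))
            handle.write("\n")
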
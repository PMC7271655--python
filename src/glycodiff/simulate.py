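"""Synthetic proteomes and multiplexed quantification tables with ground truth.

The generator starts at the quantified-peptide level (no spectra): it builds
a random proteome, digests it with trypsin, plants isoform-specific PTM
effects on a chosen subset of peptides, and emits per-channel abundances
with multiplicative log-normal noise.  Every planted effect is recorded in a
:class:`~glycodiff.model.SyntheticTruth` registry so that downstream calls
can be scored for precision and recall.

Abundance model
---------------
Each peptide draws a base abundance ``A = 10**N(mu, sigma)``.  A channel
belonging to clone ``c`` of knockout isoform ``k`` expects ``A * r`` if the
peptide hosts a site planted for ``k`` (``r`` = the true effect ratio) and
``A`` otherwise; WT channels always expect ``A``.  Every channel value is
then multiplied by ``10**N(0, noise_sd_log10)``.  With zero noise, planted
peptides therefore have KO/WT ratio exactly the effect ratio and all other
peptides exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pyteomics import parser as _pyt_parser

from .designs import SimulationDesign
from .errors import CapacityError, InvalidParameterError, ParseError
from .model import (
    AMINO_ACIDS,
    GLYCO_RESIDUES,
    ISOFORMS,
    Modification,
    PHOSPHO_RESIDUES,
    ProteinEntry,
    QuantifiedPeptide,
    SyntheticTruth,
    TruthEntry,
)

# Average amino-acid composition of the generated proteomes, loosely based on
# the frequencies seen in vertebrate reference proteomes.  Values are
# renormalized at draw time, so they only need to be proportional.
RESIDUE_COMPOSITION: dict[str, float] = {
    "A": 7.0, "C": 2.0, "D": 5.4, "E": 6.8, "F": 3.9,
    "G": 6.6, "H": 2.6, "I": 4.9, "K": 5.7, "L": 9.9,
    "M": 2.4, "N": 3.9, "P": 6.2, "Q": 4.7, "R": 5.6,
    "S": 8.3, "T": 5.3, "V": 6.0, "W": 1.2, "Y": 2.6,
}

# Plain Keil rule: cleave after K/R unless followed by P.  (The full Expasy
# pattern adds WK|P / MR|P exception cleavages; this pipeline uses the
# simple convention.)
_TRYPSIN = r"[KR](?!P)"


def composition_probabilities() -> tuple[str, np.ndarray]:
    letters = "".join(sorted(RESIDUE_COMPOSITION))
    weights = np.array([RESIDUE_COMPOSITION[a] for a in letters], dtype=float)
    return letters, weights / weights.sum()


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    seed: int | np.random.Generator,
) -> list[ProteinEntry]:
    """Generate ``n_proteins`` random protein sequences.

    Sequences are drawn i.i.d. from :data:`RESIDUE_COMPOSITION` and redrawn
    until they contain at least one K/R (so trypsin produces fragments) and
    at least one S/T (so glycosylation is possible).  Deterministic for a
    fixed seed.
    """
    if n_proteins < 1:
        raise InvalidParameterError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise InvalidParameterError("length_range must be a positive interval")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    letters, probs = composition_probabilities()
    letter_arr = np.array(list(letters))
    width = max(4, len(str(n_proteins)))
    proteome: list[ProteinEntry] = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        while True:
            seq = "".join(rng.choice(letter_arr, size=length, p=probs))
            if (set(seq) & {"K", "R"}) and (set(seq) & GLYCO_RESIDUES):
                break
        proteome.append(
            ProteinEntry(
                accession=f"SYN{i + 1:0{width}d}",
                sequence=seq,
                description="synthetic protein",
            )
        )
    return proteome


def digest_protein(
    sequence: str, missed_cleavages: int
) -> list[tuple[str, int]]:
    """Tryptic digestion: cleave after K/R except before P.

    Returns ``(peptide, start)`` pairs with 1-based start positions,
    including all concatenations of up to ``missed_cleavages + 1`` adjacent
    fully-cleaved fragments, ordered by start then length.
    """
    if not 0 <= missed_cleavages <= 2:
        raise InvalidParameterError("missed_cleavages must be 0-2")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad or not sequence:
        raise ParseError(f"invalid residue(s) {sorted(bad)} in sequence")
    # icleave duplicates the terminal fragment when the chain ends at a
    # cleavage site; a set keeps one copy of each (peptide, start) pair
    out = {
        (pep, start + 1)
        for start, pep in _pyt_parser.icleave(
            sequence, _TRYPSIN, missed_cleavages=missed_cleavages
        )
        if pep
    }
    return sorted(out, key=lambda item: (item[1], len(item[0])))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _occurrence_count(haystack: str, needle: str) -> int:
    """Number of (possibly overlapping) occurrences of ``needle``."""
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


@dataclass(frozen=True)
class _PeptideSlot:
    """A digestible peptide eligible to host planted sites."""

    accession: str
    peptide: str
    start: int  # 1-based in protein
    candidate_offsets: tuple[int, ...]  # 1-based within peptide


def _eligible_peptides(
    proteome: list[ProteinEntry], design: SimulationDesign, phospho: bool
) -> list[_PeptideSlot]:
    """Fully-cleaved peptides that locate uniquely and carry >=1 candidate
    residue, restricted to the observable length window."""
    lo, hi = design.peptide_length_range
    residues = PHOSPHO_RESIDUES if phospho else GLYCO_RESIDUES
    counts: dict[str, int] = {}
    per_protein: list[tuple[ProteinEntry, str, int]] = []
    for protein in proteome:
        for pep, start in digest_protein(protein.sequence, 0):
            if not lo <= len(pep) <= hi:
                continue
            counts[pep] = counts.get(pep, 0) + 1
            per_protein.append((protein, pep, start))
    slots = []
    sequences = {p.accession: p.sequence for p in proteome}
    for protein, pep, start in per_protein:
        if counts[pep] != 1:
            continue  # shared across proteins or repeated: skip for planting
        if _occurrence_count(sequences[protein.accession], pep) != 1:
            continue  # occurs again at a non-tryptic position
        offsets = tuple(
            i + 1 for i, aa in enumerate(pep) if aa in residues
        )
        if offsets:
            slots.append(
                _PeptideSlot(protein.accession, pep, start, offsets)
            )
    return slots


def plant_sites(
    proteome: list[ProteinEntry],
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Choose the planted isoform-specific sites and record them as truth.

    Glyco designs honour ``fraction_multisite``: that fraction of each
    isoform's sites (round-half-up, bumped to the next even number because
    multi-glycan sites are planted in pairs on a shared peptide) lie on
    peptides carrying two glycans.  Phospho designs plant one site per
    peptide.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    phospho = design.kind == "phospho_tmt"
    slots = _eligible_peptides(proteome, design, phospho)
    n = design.n_planted_per_isoform

    if phospho:
        n_multi = 0
    else:
        n_multi = _round_half_up(design.fraction_multisite * n)
        if n_multi % 2:  # multi-class sites are planted in pairs
            n_multi += 1
        max_even = n - (n % 2)
        n_multi = min(n_multi, max_even)
    n_single = n - n_multi

    multi_slots = [s for s in slots if len(s.candidate_offsets) >= 2]
    need_multi = 3 * (n_multi // 2)
    need_single = 3 * n_single
    if len(multi_slots) < need_multi or len(slots) < need_multi + need_single:
        raise CapacityError(
            f"proteome offers {len(slots)} candidate peptides "
            f"({len(multi_slots)} with >=2 candidate residues) but the design "
            f"needs {need_multi + need_single} ({need_multi} multi-glycan)"
        )

    order = list(rng.permutation(len(slots)))
    multi_first = sorted(order, key=lambda i: len(slots[i].candidate_offsets) < 2)
    taken: set[int] = set()
    entries: list[TruthEntry] = []
    for isoform in ISOFORMS:
        # pairs of multi-glycan sites: two glycans on one peptide
        pairs = n_multi // 2
        for idx in multi_first:
            if pairs == 0:
                break
            if idx in taken or len(slots[idx].candidate_offsets) < 2:
                continue
            slot = slots[idx]
            offs = rng.choice(
                len(slot.candidate_offsets), size=2, replace=False
            )
            for off_i in sorted(offs):
                off = slot.candidate_offsets[off_i]
                entries.append(
                    TruthEntry(
                        accession=slot.accession,
                        position=slot.start + off - 1,
                        isoform=isoform,
                        effect_ratio=design.effect_ratio,
                        multiplicity="multiple",
                        peptide=slot.peptide,
                        peptide_start=slot.start,
                    )
                )
            taken.add(idx)
            pairs -= 1
        singles = n_single
        for idx in order:
            if singles == 0:
                break
            if idx in taken:
                continue
            slot = slots[idx]
            off = slot.candidate_offsets[
                int(rng.integers(len(slot.candidate_offsets)))
            ]
            entries.append(
                TruthEntry(
                    accession=slot.accession,
                    position=slot.start + off - 1,
                    isoform=isoform,
                    effect_ratio=design.effect_ratio,
                    multiplicity="single",
                    peptide=slot.peptide,
                    peptide_start=slot.start,
                )
            )
            taken.add(idx)
            singles -= 1
    return SyntheticTruth(entries=tuple(entries))


def _planted_peptide_records(
    truth: SyntheticTruth, design: SimulationDesign, glyco_kind: str
) -> list[tuple[QuantifiedPeptide, str, float]]:
    """One record per planted peptide: (record, owning isoform, effect)."""
    groups: dict[tuple[str, str, int], list[TruthEntry]] = {}
    for entry in truth.entries:
        groups.setdefault(
            (entry.accession, entry.peptide, entry.peptide_start), []
        ).append(entry)
    phospho = design.kind == "phospho_tmt"
    out = []
    for (acc, pep, start), members in sorted(groups.items()):
        isoforms = {m.isoform for m in members}
        if len(isoforms) != 1:
            raise InvalidParameterError(
                f"peptide {pep} hosts sites for more than one isoform"
            )
        kind = "Phospho" if phospho else glyco_kind
        mods = tuple(
            Modification(kind, m.position - start + 1)
            for m in sorted(members, key=lambda m: m.position)
        )
        record = QuantifiedPeptide(
            peptide=pep,
            accession=acc,
            start=start,
            modifications=mods,
            channel_values={},
            source_method=design.source_method,
        )
        out.append((record, members[0].isoform, members[0].effect_ratio))
    return out


def _background_peptide_records(
    proteome: list[ProteinEntry],
    truth: SyntheticTruth,
    design: SimulationDesign,
    glyco_kind: str,
    rng: np.random.Generator,
) -> list[QuantifiedPeptide]:
    planted_peptides = {(e.accession, e.peptide) for e in truth.entries}
    phospho = design.kind == "phospho_tmt"
    residues = PHOSPHO_RESIDUES if phospho else GLYCO_RESIDUES
    lo, hi = design.peptide_length_range
    out: list[QuantifiedPeptide] = []
    for protein in proteome:
        for pep, start in digest_protein(
            protein.sequence, design.missed_cleavages
        ):
            if not lo <= len(pep) <= hi:
                continue
            if (protein.accession, pep) in planted_peptides:
                continue
            offsets = [i + 1 for i, aa in enumerate(pep) if aa in residues]
            if not offsets:
                continue
            off = offsets[int(rng.integers(len(offsets)))]
            kind = "Phospho" if phospho else glyco_kind
            out.append(
                QuantifiedPeptide(
                    peptide=pep,
                    accession=protein.accession,
                    start=start,
                    modifications=(Modification(kind, off),),
                    channel_values={},
                    source_method=design.source_method,
                )
            )
    return out


def simulate_quant_table(
    proteome: list[ProteinEntry],
    truth: SyntheticTruth,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> tuple[list[QuantifiedPeptide], SyntheticTruth]:
    """Fill in per-channel abundances for planted and background peptides.

    The glycan composition follows the design: the TMT glyco screen (WT
    background, Jacalin enrichment) carries HexHexNAc, the dimethyl screen
    (SimpleCell background, VVA enrichment) carries HexNAc.
    """
    rng = np.random.default_rng(design.seed + 1) if rng is None else rng
    glyco_kind = "HexNAc" if design.kind == "dimethyl_pair" else "HexHexNAc"
    planted = _planted_peptide_records(truth, design, glyco_kind)
    background = _background_peptide_records(
        proteome, truth, design, glyco_kind, rng
    )
    records: list[QuantifiedPeptide] = []
    channels = design.channels
    for record, isoform, effect in planted + [(r, None, 1.0) for r in background]:
        base = 10.0 ** rng.normal(design.abundance_log10_mean, design.abundance_log10_sd)
        values: dict[str, float | None] = {}
        for chan in channels:
            expected = base
            if isoform is not None and chan.group == isoform:
                expected = base * effect
                if design.clone_jitter_sd_log10 > 0:
                    expected *= 10.0 ** rng.normal(0.0, design.clone_jitter_sd_log10)
            noise = 10.0 ** rng.normal(0.0, design.noise_sd_log10)
            values[chan.label] = expected * noise
        if design.missing_rate > 0:
            for chan in channels:
                if rng.random() < design.missing_rate:
                    values[chan.label] = None
        record.channel_values = values
        records.append(record)
    return records, truth


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[list[ProteinEntry], list[QuantifiedPeptide], SyntheticTruth]:
    """Full generator run: proteome -> planted truth -> quant table."""
    rng = np.random.default_rng(design.seed)
    proteome = generate_proteome(design.n_proteins, design.length_range, rng)
    truth = plant_sites(proteome, design, rng)
    records, truth = simulate_quant_table(proteome, truth, design, rng)
    return proteome, records, truth


def simulate_dimethyl_set(
    design: SimulationDesign,
) -> tuple[list[ProteinEntry], dict[str, list[QuantifiedPeptide]], SyntheticTruth]:
    """Three isogenic dimethyl pairs (one per isoform) over one shared truth.

    The planted registry covers all three isoforms; each pair only shows the
    effect of its own isoform's sites, everything else stays at ratio 1.
    """
    if design.kind != "dimethyl_pair":
        raise InvalidParameterError("simulate_dimethyl_set needs a dimethyl design")
    rng = np.random.default_rng(design.seed)
    proteome = generate_proteome(design.n_proteins, design.length_range, rng)
    truth = plant_sites(proteome, design, rng)
    tables: dict[str, list[QuantifiedPeptide]] = {}
    for isoform in ISOFORMS:
        pair = SimulationDesign(
            **{**design.__dict__, "dimethyl_isoform": isoform}
        )
        records, _ = simulate_quant_table(proteome, truth, pair, rng)
        tables[isoform] = records
    return proteome, tables, truth


def null_phospho_ratio_rows(
    n_peptides: int, noise_sd_log10: float, seed: int
):
    """Ratio rows for a null phospho screen: no planted effects, independent
    normal log-ratio noise per contrast (clone contrasts ~ N(0, sd); the
    WT2/WT1 contrast ~ N(0, sd*sqrt(2)) since it is a difference of two
    replicate channels)."""
    from .model import RatioRow  # local import to avoid cycle at module load

    design = SimulationDesign(kind="phospho_tmt", noise_sd_log10=noise_sd_log10)
    rng = np.random.default_rng(seed)
    contrasts = [design.contrast_label(c) for c in design.ko_channels]
    letters = "ACDEFGHILMNQVWY"  # no K/R/S/T: unique inert peptide bodies

    def unique_peptide(i: int) -> str:
        body = []
        while True:
            body.append(letters[i % len(letters)])
            i //= len(letters)
            if i == 0:
                break
        return "S" + "".join(body) + "K"

    rows = []
    for i in range(n_peptides):
        logs = {c: rng.normal(0.0, noise_sd_log10) for c in contrasts}
        logs["WT2/WT1"] = rng.normal(0.0, noise_sd_log10 * math.sqrt(2.0))
        record = QuantifiedPeptide(
            peptide=unique_peptide(i),
            accession=f"NULL{i + 1:06d}",
            start=None,
            modifications=(Modification("Phospho", None),),
            channel_values={},
            source_method="tmt_phospho",
        )
        rows.append(
            RatioRow(
                record=record,
                ratios={k: 10.0 ** v for k, v in logs.items()},
                log10_ratios=logs,
            )
        )
    return rows
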
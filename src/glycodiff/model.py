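"""Core domain records shared by every pipeline stage.

Coordinate conventions
----------------------
All protein positions are 1-based inclusive; within-peptide modification
positions are 1-based relative to the peptide's first residue.  A site with
more than one candidate position is *ambiguous* and displayed with the
semicolon convention (``"402;403"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GLYCO_KINDS = frozenset({"HexNAc", "HexHexNAc"})
PHOSPHO_KIND = "Phospho"
MOD_KINDS = GLYCO_KINDS | {PHOSPHO_KIND}

#: Residues eligible to carry each class of modification.
GLYCO_RESIDUES = frozenset("ST")
PHOSPHO_RESIDUES = frozenset("STY")

ISOFORMS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class ProteinEntry:
    """A protein sequence; the coordinate frame for all site positions."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class Modification:
    """One modification on a peptide.

    ``position`` is the 1-based residue within the peptide, or ``None`` when
    the glycan/phosphate count is known but the residue is not localized.
    """

    kind: str
    position: int | None

    def __post_init__(self) -> None:
        if self.kind not in MOD_KINDS:
            raise ValueError(f"unknown modification kind {self.kind!r}")
        if self.position is not None and self.position < 1:
            raise ValueError("modification positions are 1-based")

    @property
    def localized(self) -> bool:
        return self.position is not None

    @property
    def is_glyco(self) -> bool:
        return self.kind in GLYCO_KINDS


@dataclass
class QuantifiedPeptide:
    """A quantified peptide observation — the atomic input record.

    ``channel_values`` maps channel label to non-negative abundance; ``None``
    marks a missing value (empty cell in the TSV).
    """

    peptide: str
    accession: str
    start: int | None
    modifications: tuple[Modification, ...]
    channel_values: dict[str, float | None]
    source_method: str = "tmt_glyco"

    def __post_init__(self) -> None:
        for mod in self.modifications:
            if mod.position is not None and mod.position > len(self.peptide):
                raise ValueError(
                    f"{self.peptide}: modification position {mod.position} "
                    f"beyond peptide length {len(self.peptide)}"
                )
            if mod.position is not None:
                residue = self.peptide[mod.position - 1]
                allowed = GLYCO_RESIDUES if mod.is_glyco else PHOSPHO_RESIDUES
                if residue not in allowed:
                    raise ValueError(
                        f"{self.peptide}: {mod.kind} at position "
                        f"{mod.position} sits on {residue}, not one of "
                        f"{sorted(allowed)}"
                    )

    @property
    def glyco_mods(self) -> tuple[Modification, ...]:
        return tuple(m for m in self.modifications if m.is_glyco)

    @property
    def phospho_mods(self) -> tuple[Modification, ...]:
        return tuple(m for m in self.modifications if not m.is_glyco)


@dataclass
class RatioRow:
    """Per-peptide contrast ratios on linear and log10 scales.

    ``undefined`` lists contrasts whose denominator was zero/negative or
    missing; those contrasts are absent from ``ratios``, never zero.
    """

    record: QuantifiedPeptide
    ratios: dict[str, float]
    log10_ratios: dict[str, float]
    undefined: tuple[str, ...] = ()


@dataclass(frozen=True)
class SiteCall:
    """A protein-anchored PTM site, possibly a set of alternative positions."""

    accession: str
    positions: tuple[int, ...]
    kind: str  # "glyco" | "phospho"
    multiplicity: str  # "single" | "multiple"
    peptides: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("a SiteCall needs at least one position")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        if self.kind not in ("glyco", "phospho"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.multiplicity not in ("single", "multiple"):
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")

    @property
    def ambiguous(self) -> bool:
        return len(self.positions) > 1

    @property
    def display(self) -> str:
        return ";".join(str(p) for p in self.positions)

    @property
    def key(self) -> str:
        return f"{self.accession}:{self.display}"


def site_key(call: SiteCall) -> str:
    """Canonical key ``accession:pos1;pos2;...`` for set operations."""
    return call.key


@dataclass
class DifferentialCall:
    """A site or peptide flagged by a selection rule."""

    target: str  # site key or peptide sequence
    isoform: str
    direction: str  # "down" | "up"
    rule: str  # "phospho_2sd" | "glyco_3clone" | "dimethyl" | "anova_q"
    clone_ratios: dict[str, float] = field(default_factory=dict)
    filters_passed: tuple[str, ...] = ()
    protein_quant: float | None = None  # None = not detected

    def __post_init__(self) -> None:
        if self.isoform not in ISOFORMS:
            raise ValueError(f"unknown isoform {self.isoform!r}")
        if self.direction not in ("down", "up"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.filters_passed:
            raise ValueError("emitted calls must carry a filter audit trail")


@dataclass(frozen=True)
class TruthEntry:
    """One planted effect: a site, the isoform that owns it, the true ratio."""

    accession: str
    position: int
    isoform: str
    effect_ratio: float
    multiplicity: str
    peptide: str
    peptide_start: int

    @property
    def key(self) -> str:
        return f"{self.accession}:{self.position}"


@dataclass
class SyntheticTruth:
    """Registry of planted effects used for recovery scoring."""

    entries: tuple[TruthEntry, ...]

    def by_isoform(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {iso: set() for iso in ISOFORMS}
        for entry in self.entries:
            out[entry.isoform].add(entry.key)
        return out

    def __len__(self) -> int:
        return len(self.entries)
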
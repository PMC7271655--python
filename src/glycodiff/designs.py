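"""Experimental designs: channel layouts and simulation parameters.

Three multiplexing designs are supported, mirroring the isogenic
keratinocyte KO experiments the pipeline was written for:

``glyco_tmt10``
    TMT 10-plex: one WT channel plus three clones of each of the three
    GalNAc-T knockouts (T1, T2, T3), all quantified against the single WT.
``phospho_tmt``
    TMT with two WT biological replicates plus two clones of each KO;
    KO/WT ratios use the mean of the two WT channels, and WT2/WT1 is kept
    as its own contrast for the empirical null.
``dimethyl_pair``
    Two-channel stable-isotope dimethyl labeling (light WT, medium KO);
    one isogenic pair per run, one pair per isoform.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError
from .model import ISOFORMS

DESIGN_KINDS = ("glyco_tmt10", "phospho_tmt", "dimethyl_pair")


@dataclass(frozen=True)
class Channel:
    """A quantification channel and the sample group it carries."""

    label: str
    group: str  # "WT" or an isoform "T1"/"T2"/"T3"
    replicate: int  # WT replicate number, or KO clone number

    @property
    def is_wt(self) -> bool:
        return self.group == "WT"


def _glyco_tmt10_channels() -> tuple[Channel, ...]:
    chans = [Channel("WT", "WT", 1)]
    for iso in ISOFORMS:
        for clone in (1, 2, 3):
            chans.append(Channel(f"{iso}.c{clone}", iso, clone))
    return tuple(chans)


def _phospho_tmt_channels() -> tuple[Channel, ...]:
    chans = [Channel("WT1", "WT", 1), Channel("WT2", "WT", 2)]
    for iso in ISOFORMS:
        for clone in (1, 2):
            chans.append(Channel(f"{iso}.c{clone}", iso, clone))
    return tuple(chans)


def _dimethyl_channels(isoform: str) -> tuple[Channel, ...]:
    return (Channel("WT", "WT", 1), Channel(isoform, isoform, 1))


@dataclass
class SimulationDesign:
    """Everything the simulator needs; defaults are the standard study
    conditions used throughout the test-suite and the acceptance run.

    Parameters
    ----------
    kind:
        One of ``glyco_tmt10``, ``phospho_tmt``, ``dimethyl_pair``.
    n_proteins, length_range:
        Proteome size and residue-length interval for generated proteins.
    n_planted_per_isoform:
        Number of true isoform-specific sites planted per isoform.
    effect_ratio:
        True KO/WT ratio on planted targets (0.2 = five-fold loss).
    noise_sd_log10:
        SD of multiplicative log10-normal noise applied per channel value.
    fraction_multisite:
        Fraction of planted glycosites that sit on peptides carrying more
        than one glycan (glyco designs only).
    missed_cleavages:
        Tryptic missed cleavages allowed for background peptides (0-2).
    dimethyl_isoform:
        Which KO the medium channel carries in a dimethyl pair.
    """

    kind: str = "glyco_tmt10"
    n_proteins: int = 300
    length_range: tuple[int, int] = (150, 450)
    n_planted_per_isoform: int = 60
    effect_ratio: float = 0.2
    noise_sd_log10: float = 0.05
    missed_cleavages: int = 0
    fraction_multisite: float = 0.3
    seed: int = 42
    peptide_length_range: tuple[int, int] = (6, 40)
    abundance_log10_mean: float = 6.0
    abundance_log10_sd: float = 0.5
    clone_jitter_sd_log10: float = 0.0
    missing_rate: float = 0.0
    dimethyl_isoform: str = "T1"

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise InvalidParameterError(f"unknown design kind {self.kind!r}")
        if self.n_proteins < 1:
            raise InvalidParameterError("n_proteins must be >= 1")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise InvalidParameterError("length_range must be a positive interval")
        if self.n_planted_per_isoform < 0:
            raise InvalidParameterError("n_planted_per_isoform must be >= 0")
        if self.effect_ratio <= 0:
            raise InvalidParameterError("effect_ratio must be > 0")
        if self.noise_sd_log10 < 0:
            raise InvalidParameterError("noise_sd_log10 must be >= 0")
        if not 0 <= self.missed_cleavages <= 2:
            raise InvalidParameterError("missed_cleavages must be 0-2")
        if not 0.0 <= self.fraction_multisite <= 1.0:
            raise InvalidParameterError("fraction_multisite must be in [0,1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise InvalidParameterError("missing_rate must be in [0,1]")
        if self.dimethyl_isoform not in ISOFORMS:
            raise InvalidParameterError(
                f"dimethyl_isoform must be one of {ISOFORMS}"
            )

    @property
    def channels(self) -> tuple[Channel, ...]:
        if self.kind == "glyco_tmt10":
            return _glyco_tmt10_channels()
        if self.kind == "phospho_tmt":
            return _phospho_tmt_channels()
        return _dimethyl_channels(self.dimethyl_isoform)

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.channels)

    @property
    def wt_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.is_wt)

    @property
    def ko_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if not c.is_wt)

    @property
    def source_method(self) -> str:
        return {
            "glyco_tmt10": "tmt_glyco",
            "phospho_tmt": "tmt_phospho",
            "dimethyl_pair": "dimethyl",
        }[self.kind]

    @property
    def clones_per_isoform(self) -> int:
        return {"glyco_tmt10": 3, "phospho_tmt": 2, "dimethyl_pair": 1}[self.kind]

    def contrast_label(self, channel: Channel) -> str:
        """Contrast name for a KO channel (denominator is always WT)."""
        return f"{channel.label}/WT"

    def isoform_contrasts(self, isoform: str) -> tuple[str, ...]:
        return tuple(
            self.contrast_label(c) for c in self.ko_channels if c.group == isoform
        )
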
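"""Differential selection rules.

Four rules are implemented:

* **phospho_2sd** — a phosphopeptide is differential for a knockout when
  its log10 KO/WT ratio lies more than ``sd_multiplier`` (default 2)
  standard deviations from the contrast-family median in *both* clones, on
  the same side, while its own WT2/WT1 ratio stays inside the central-95%
  interval of all WT2/WT1 ratios (the empirical replicate null).
* **glyco_3clone** — a glycosite is differential when its KO/WT ratio is
  consistently changed in all three clones (<= 0.5 down, >= 2.0 up by
  default), with an isoform-selectivity classifier and a protein-level
  abundance control (mean clone ratio > 0.75) on top.
* **dimethyl** — simple per-pair thresholding of the medium/light ratio.
* **anova_q** — one-way ANOVA across KO groups on log10 site
  quantifications, selected at a Benjamini-Hochberg q <= 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

from .designs import SimulationDesign
from .errors import ConfigurationError, InsufficientDataError, InvalidParameterError
from .model import ISOFORMS, DifferentialCall, RatioRow
from .quant_io import WT_CONTRAST

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class CallingParams:
    """Thresholds for all selection rules (defaults follow the pipeline's
    standard configuration)."""

    down_threshold: float = 0.5
    up_threshold: float = 2.0
    protein_quant_threshold: float = 0.75
    sd_multiplier: float = 2.0
    wt_interval_coverage: float = 0.95
    anova_q: float = 0.1
    null_mode: str = "empirical"  # or "normal"
    robust_sd: bool = False

    def __post_init__(self) -> None:
        if self.down_threshold <= 0 or self.up_threshold <= 0:
            raise InvalidParameterError("thresholds must be positive")
        if not 0 < self.wt_interval_coverage < 1:
            raise InvalidParameterError("wt_interval_coverage must be in (0,1)")


@dataclass
class NullModel:
    """Per-contrast-family ratio distribution summaries plus the central
    WT2/WT1 replicate interval."""

    median_log10: dict[str, float]
    sd_log10: dict[str, float]
    wt_interval: tuple[float, float]
    mode: str = "empirical"

    def __post_init__(self) -> None:
        for name, sd in self.sd_log10.items():
            if sd < 0:
                raise InvalidParameterError(f"sd for {name!r} is negative")
        lo, hi = self.wt_interval
        if lo > hi:
            raise InvalidParameterError("wt_interval bounds out of order")


@dataclass
class SkipCounter:
    """Audit of records a rule could not evaluate (never imputed)."""

    counts: dict[str, int] = field(default_factory=dict)

    def bump(self, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Distribution summaries and the WT null

def ratio_distribution_stats(
    log_ratios, robust: bool = False
) -> tuple[float, float]:
    """Median and spread of a log-ratio family.

    The spread is the sample standard deviation (n-1 denominator) or, in
    robust mode, 1.4826 x the median absolute deviation.
    """
    values = np.asarray(list(log_ratios), dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise InsufficientDataError(
            f"need >=3 finite values, got {values.size}"
        )
    median = float(np.median(values))
    if robust:
        sd = float(1.4826 * np.median(np.abs(values - median)))
    else:
        sd = float(np.std(values, ddof=1))
    return median, sd


def build_null(
    wt_ratio_logs,
    mode: str = "empirical",
    coverage: float = 0.95,
) -> tuple[float, float]:
    """Central interval of WT2/WT1 log10 ratios.

    Empirical mode takes the (2.5th, 97.5th) percentile interval (linear
    interpolation); normal mode returns ``mean +/- 1.959964*sd``.
    """
    values = np.asarray(list(wt_ratio_logs), dtype=float)
    values = values[np.isfinite(values)]
    alpha = (1.0 - coverage) / 2.0
    if mode == "empirical":
        if values.size < 20:
            raise InsufficientDataError(
                f"empirical null needs >=20 WT2/WT1 values (got {values.size});"
                " use normal mode"
            )
        lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
        return float(lo), float(hi)
    if mode == "normal":
        if values.size < 3:
            raise InsufficientDataError("normal mode needs >=3 values")
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1))
        z = float(_scipy_stats.norm.ppf(1 - alpha))
        return mean - z * sd, mean + z * sd
    raise InvalidParameterError(f"unknown null mode {mode!r}")


def fit_null_model(
    ratio_rows: list[RatioRow],
    design: SimulationDesign,
    params: CallingParams | None = None,
) -> NullModel:
    """Fit per-contrast medians/SDs and the WT2/WT1 interval from one run."""
    params = params or CallingParams()
    if design.kind != "phospho_tmt":
        raise ConfigurationError("the phospho null needs a phospho_tmt design")
    contrasts = [design.contrast_label(c) for c in design.ko_channels]
    median_log10: dict[str, float] = {}
    sd_log10: dict[str, float] = {}
    for contrast in contrasts:
        logs = [
            row.log10_ratios[contrast]
            for row in ratio_rows
            if contrast in row.log10_ratios
        ]
        median_log10[contrast], sd_log10[contrast] = ratio_distribution_stats(
            logs, robust=params.robust_sd
        )
    wt_logs = [
        row.log10_ratios[WT_CONTRAST]
        for row in ratio_rows
        if WT_CONTRAST in row.log10_ratios
    ]
    interval = build_null(
        wt_logs, mode=params.null_mode, coverage=params.wt_interval_coverage
    )
    return NullModel(median_log10, sd_log10, interval, mode=params.null_mode)


# ---------------------------------------------------------------------------
# Phospho rule

def call_phospho_differential(
    ratio_rows: list[RatioRow],
    null: NullModel,
    design: SimulationDesign,
    params: CallingParams | None = None,
    skips: SkipCounter | None = None,
) -> list[DifferentialCall]:
    """Two-clone 2-SD rule gated by the WT replicate interval.

    A peptide is called for isoform ``k`` iff both clone log10 ratios lie
    strictly beyond ``median +/- sd_multiplier*sd`` on the same side and its
    WT2/WT1 log10 ratio lies within the null interval (inclusive bounds).
    Peptides missing a required contrast are skipped and counted.
    """
    params = params or CallingParams()
    if design.kind != "phospho_tmt":
        raise ConfigurationError("call_phospho_differential needs phospho_tmt")
    for contrast in (design.contrast_label(c) for c in design.ko_channels):
        if contrast not in null.median_log10:
            raise ConfigurationError(
                f"null model lacks contrast family {contrast!r}"
            )
    skips = skips if skips is not None else SkipCounter()
    lo, hi = null.wt_interval
    calls: list[DifferentialCall] = []
    for row in ratio_rows:
        wt_log = row.log10_ratios.get(WT_CONTRAST)
        if wt_log is None:
            skips.bump("missing_wt_contrast")
            continue
        wt_ok = lo <= wt_log <= hi
        for isoform in ISOFORMS:
            contrasts = design.isoform_contrasts(isoform)
            logs = [row.log10_ratios.get(c) for c in contrasts]
            if any(v is None for v in logs):
                skips.bump(f"missing_clone_contrast_{isoform}")
                continue
            sides = []
            for contrast, value in zip(contrasts, logs):
                med = null.median_log10[contrast]
                sd = null.sd_log10[contrast]
                if value < med - params.sd_multiplier * sd:
                    sides.append(-1)
                elif value > med + params.sd_multiplier * sd:
                    sides.append(+1)
                else:
                    sides.append(0)
            if 0 in sides or len(set(sides)) != 1:
                continue
            if not wt_ok:
                continue
            direction = "down" if sides[0] < 0 else "up"
            calls.append(
                DifferentialCall(
                    target=row.record.peptide,
                    isoform=isoform,
                    direction=direction,
                    rule="phospho_2sd",
                    clone_ratios={c: row.ratios[c] for c in contrasts},
                    filters_passed=(
                        f"both_clones_beyond_{params.sd_multiplier}sd",
                        "same_side",
                        "within_wt_interval",
                    ),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Glyco TMT rule

def call_glyco_differential_tmt(
    site_ratio_table: dict[str, dict[str, list[float]]],
    params: CallingParams | None = None,
    skips: SkipCounter | None = None,
) -> list[DifferentialCall]:
    """Three-clone consistency rule on a site ratio table.

    ``site_ratio_table`` maps site key -> isoform -> clone ratios (linear
    scale).  A site is changed for an isoform iff all three clone ratios
    are <= ``down_threshold`` (down) or all three >= ``up_threshold`` (up).
    Sites with fewer than three clone ratios for an isoform are skipped and
    counted, never imputed.
    """
    params = params or CallingParams()
    skips = skips if skips is not None else SkipCounter()
    calls: list[DifferentialCall] = []
    for key in sorted(site_ratio_table):
        per_isoform = site_ratio_table[key]
        for isoform in ISOFORMS:
            clones = per_isoform.get(isoform)
            if clones is None:
                continue  # isoform not measured for this site
            if len(clones) < 3:
                skips.bump(f"fewer_than_3_clones_{isoform}")
                continue
            if all(r <= params.down_threshold for r in clones):
                direction = "down"
            elif all(r >= params.up_threshold for r in clones):
                direction = "up"
            else:
                continue
            calls.append(
                DifferentialCall(
                    target=key,
                    isoform=isoform,
                    direction=direction,
                    rule="glyco_3clone",
                    clone_ratios={
                        f"{isoform}.c{j + 1}/WT": r for j, r in enumerate(clones)
                    },
                    filters_passed=("consistent_in_all_3_clones",),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Isoform selectivity and the protein-level control

def protein_level_control(
    protein_clone_ratios, threshold: float = 0.75
) -> tuple[bool, str]:
    """Protein abundance gate: mean of clone KO/WT ratios must exceed the
    threshold.  Not-detected proteins pass with an audit flag (as in
    site tables that mark them "1 or ND")."""
    if protein_clone_ratios is None or (
        hasattr(protein_clone_ratios, "__len__") and len(protein_clone_ratios) == 0
    ):
        return True, "protein_not_detected"
    mean = float(np.mean(list(protein_clone_ratios)))
    if mean > threshold:
        return True, f"protein_quant_mean_{mean:.3f}_above_{threshold}"
    return False, f"protein_quant_mean_{mean:.3f}_at_or_below_{threshold}"


@dataclass
class SelectivityResult:
    """Outcome of the isoform-selectivity classifier for one site."""

    status: str  # "selective" | "shared" | "unchanged"
    isoform: str | None = None  # set when selective
    shared_isoforms: frozenset[str] = frozenset()
    audit: tuple[str, ...] = ()


def classify_isoform_selectivity(
    per_isoform_ratios: dict[str, list[float]],
    protein_quants: dict[str, list[float] | None] | None = None,
    params: CallingParams | None = None,
    clones_required: int = 3,
) -> SelectivityResult:
    """Selective / shared / unchanged classification of one glycosite.

    ``selective(k)``: all clone ratios <= down_threshold for isoform ``k``,
    every available clone ratio of every other isoform > down_threshold,
    and the protein-level control passes for ``k``.  ``shared``: two or
    more isoforms meet the all-clones-down criterion.  Partial data
    downgrade to ``unchanged`` with an audit note.
    """
    params = params or CallingParams()
    protein_quants = protein_quants or {}
    audit: list[str] = []
    down_isoforms = []
    for isoform in ISOFORMS:
        clones = per_isoform_ratios.get(isoform, [])
        if len(clones) < clones_required:
            audit.append(f"partial_data_{isoform}")
            continue
        if all(r <= params.down_threshold for r in clones):
            down_isoforms.append(isoform)
    if len(down_isoforms) >= 2:
        return SelectivityResult(
            status="shared",
            shared_isoforms=frozenset(down_isoforms),
            audit=tuple(audit),
        )
    if len(down_isoforms) == 1:
        isoform = down_isoforms[0]
        others_ok = True
        for other in ISOFORMS:
            if other == isoform:
                continue
            clones = per_isoform_ratios.get(other, [])
            if not clones:
                audit.append(f"no_data_{other}")
                others_ok = False
                continue
            if not all(r > params.down_threshold for r in clones):
                others_ok = False
        if not others_ok:
            return SelectivityResult(status="unchanged", audit=tuple(audit))
        ok, flag = protein_level_control(
            protein_quants.get(isoform), params.protein_quant_threshold
        )
        audit.append(flag)
        if not ok:
            return SelectivityResult(status="unchanged", audit=tuple(audit))
        return SelectivityResult(
            status="selective", isoform=isoform, audit=tuple(audit)
        )
    return SelectivityResult(status="unchanged", audit=tuple(audit))


# ---------------------------------------------------------------------------
# Dimethyl rule

def call_glyco_differential_dimethyl(
    pair_ratios: dict[str, dict[str, float]],
    params: CallingParams | None = None,
) -> list[DifferentialCall]:
    """Per-pair thresholding: ``pair_ratios`` maps isoform -> site key (or
    peptide) -> KO/WT ratio.  Results across the isogenic pairs are merged
    by target key."""
    params = params or CallingParams()
    calls: list[DifferentialCall] = []
    for isoform in ISOFORMS:
        table = pair_ratios.get(isoform, {})
        for target in sorted(table):
            ratio = table[target]
            if ratio <= params.down_threshold:
                direction = "down"
            elif ratio >= params.up_threshold:
                direction = "up"
            else:
                continue
            calls.append(
                DifferentialCall(
                    target=target,
                    isoform=isoform,
                    direction=direction,
                    rule="dimethyl",
                    clone_ratios={f"{isoform}/WT": ratio},
                    filters_passed=("pair_ratio_threshold",),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# ANOVA alternative

@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    flag: str = ""


def anova_site_test(groups: list[list[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA on log10 site quantifications.

    Degenerate inputs are reported, not hidden: zero within-group variance
    with unequal means yields p = 0 with a flag; all-identical values are
    undefined and flagged for skipping.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    if len(cleaned) < 2 or any(g.size < 2 for g in cleaned):
        raise InsufficientDataError("need >=2 groups with >=2 values each")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return AnovaResult(math.nan, math.nan, flag="all_values_identical")
    within_var = sum(float(np.var(g, ddof=1)) for g in cleaned)
    if within_var == 0.0:
        return AnovaResult(math.inf, 0.0, flag="zero_within_group_variance")
    stat, p = _scipy_stats.f_oneway(*cleaned)
    return AnovaResult(float(stat), float(p))


def anova_select_sites(
    site_groups: dict[str, list[list[float]]],
    params: CallingParams | None = None,
) -> tuple[dict[str, tuple[float, float, float]], list[str]]:
    """Run the ANOVA on every site and select at BH q <= ``anova_q``.

    Returns ``{site: (F, p, q)}`` for testable sites plus the list of
    selected site keys (sorted).  Sites with degenerate inputs are tested
    with their flag semantics (p=0 counts as maximally significant;
    all-identical sites are skipped).
    """
    from .reporting import benjamini_hochberg

    params = params or CallingParams()
    keys: list[str] = []
    pvalues: list[float] = []
    stats_out: dict[str, tuple[float, float, float]] = {}
    f_by_key: dict[str, float] = {}
    for key in sorted(site_groups):
        result = anova_site_test(site_groups[key])
        if result.flag == "all_values_identical":
            continue
        keys.append(key)
        pvalues.append(result.p_value)
        f_by_key[key] = result.f_statistic
    if not keys:
        return {}, []
    qvalues = benjamini_hochberg(pvalues)
    selected = []
    for key, p, q in zip(keys, pvalues, qvalues):
        stats_out[key] = (f_by_key[key], p, q)
        if q <= params.anova_q:
            selected.append(key)
    return stats_out, sorted(selected)
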
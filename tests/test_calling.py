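"""Selection rules vs independent brute-force reimplementations."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as scipy_stats

from glycodiff import (
    CallingParams,
    Modification,
    NullModel,
    QuantifiedPeptide,
    RatioRow,
    SimulationDesign,
)
from glycodiff.calling import (
    anova_select_sites,
    anova_site_test,
    build_null,
    call_glyco_differential_dimethyl,
    call_glyco_differential_tmt,
    call_phospho_differential,
    classify_isoform_selectivity,
    fit_null_model,
    protein_level_control,
    ratio_distribution_stats,
)
from glycodiff.errors import InsufficientDataError
from glycodiff.simulate import null_phospho_ratio_rows

ISOFORMS = ("T1", "T2", "T3")
PHOSPHO = SimulationDesign(kind="phospho_tmt")
GRID = [round(0.1 * i, 10) for i in range(1, 21)]  # 0.1, 0.2, ..., 2.0


class TestRatioDistributionStats:
    def test_hand_computed_median_and_sd(self):
        median, sd = ratio_distribution_stats([-0.1, 0.0, 0.1])
        assert median == 0.0
        assert sd == pytest.approx(0.1)  # variance (0.01 + 0 + 0.01) / 2

    def test_constant_list(self):
        assert ratio_distribution_stats([0.3, 0.3, 0.3])[1] == 0.0

    def test_even_count_median_is_mean_of_central_pair(self):
        median, _ = ratio_distribution_stats([1.0, 2.0, 4.0, 10.0])
        assert median == 3.0

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            ratio_distribution_stats([0.1, 0.2])

    def test_oracle_two_pass(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            values = rng.normal(size=int(rng.integers(3, 40))).tolist()
            median, sd = ratio_distribution_stats(values)
            ordered = sorted(values)
            n = len(ordered)
            brute_median = (
                ordered[n // 2]
                if n % 2
                else (ordered[n // 2 - 1] + ordered[n // 2]) / 2
            )
            mean = sum(values) / n
            brute_sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            assert median == pytest.approx(brute_median, abs=1e-12)
            assert sd == pytest.approx(brute_sd, abs=1e-12)

    def test_robust_mode_uses_mad(self):
        values = [-1.0, 0.0, 1.0, 100.0]
        _, sd = ratio_distribution_stats(values, robust=True)
        assert sd == pytest.approx(1.4826 * 1.0)


class TestBuildNull:
    def test_empirical_interval_on_standard_normal(self):
        rng = np.random.default_rng(123)
        lo, hi = build_null(rng.normal(size=10000), mode="empirical")
        assert lo == pytest.approx(-1.96, abs=0.06)
        assert hi == pytest.approx(1.96, abs=0.06)

    def test_all_zero_ratios(self):
        assert build_null([0.0] * 30, mode="empirical") == (0.0, 0.0)

    def test_normal_mode_closed_form(self):
        # values [-1, 0, 1] have mean 0 and sample sd 1
        lo, hi = build_null([-1.0, 0.0, 1.0], mode="normal")
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)

    def test_small_sample_instructs_normal_mode(self):
        with pytest.raises(InsufficientDataError, match="normal"):
            build_null([0.1] * 10, mode="empirical")


def _constant_null(median=0.0, sd=0.1, interval=(-0.05, 0.05)) -> NullModel:
    contrasts = [PHOSPHO.contrast_label(c) for c in PHOSPHO.ko_channels]
    return NullModel(
        median_log10={c: median for c in contrasts},
        sd_log10={c: sd for c in contrasts},
        wt_interval=interval,
    )


def _phospho_row(t1_logs, wt_log, peptide="AASPK"):
    logs = {"T1.c1/WT": t1_logs[0], "T1.c2/WT": t1_logs[1], "WT2/WT1": wt_log}
    record = QuantifiedPeptide(
        peptide=peptide,
        accession="P1",
        start=None,
        modifications=(Modification("Phospho", 3),),
        channel_values={},
        source_method="tmt_phospho",
    )
    return RatioRow(
        record=record,
        ratios={k: 10.0 ** v for k, v in logs.items()},
        log10_ratios=logs,
    )


def brute_force_phospho(rows, null, design, sd_multiplier=2.0):
    """Literal restatement of the rule, independent of the implementation."""
    lo, hi = null.wt_interval
    called = []
    for row in rows:
        wt = row.log10_ratios.get("WT2/WT1")
        if wt is None or not (lo <= wt <= hi):
            continue
        for isoform in ISOFORMS:
            contrasts = design.isoform_contrasts(isoform)
            if any(c not in row.log10_ratios for c in contrasts):
                continue
            checks = []
            for c in contrasts:
                v = row.log10_ratios[c]
                m, s = null.median_log10[c], null.sd_log10[c]
                if v > m + sd_multiplier * s:
                    checks.append("up")
                elif v < m - sd_multiplier * s:
                    checks.append("down")
                else:
                    checks.append("in")
            if checks[0] != "in" and len(set(checks)) == 1:
                called.append((row.record.peptide, isoform, checks[0]))
    return sorted(called)


class TestPhosphoRule:
    def test_called_down_when_both_clones_beyond_and_wt_inside(self):
        rows = [_phospho_row((-0.5, -0.45), 0.01)]
        calls = call_phospho_differential(rows, _constant_null(), PHOSPHO)
        assert len(calls) == 1
        assert calls[0].isoform == "T1"
        assert calls[0].direction == "down"

    def test_not_called_when_one_clone_inside(self):
        rows = [_phospho_row((-0.5, -0.1), 0.01)]
        assert not call_phospho_differential(rows, _constant_null(), PHOSPHO)

    def test_not_called_when_wt_outside_interval(self):
        rows = [_phospho_row((-0.5, -0.45), 0.30)]
        assert not call_phospho_differential(rows, _constant_null(), PHOSPHO)

    def test_not_called_when_clones_disagree_on_side(self):
        rows = [_phospho_row((-0.5, 0.5), 0.01)]
        assert not call_phospho_differential(rows, _constant_null(), PHOSPHO)

    def test_oracle_equivalence_on_random_peptides(self):
        rows = null_phospho_ratio_rows(10000, 0.05, seed=314)
        null = fit_null_model(rows, PHOSPHO)
        calls = call_phospho_differential(rows, null, PHOSPHO)
        mine = sorted((c.target, c.isoform, c.direction) for c in calls)
        assert mine == brute_force_phospho(rows, null, PHOSPHO)

    def test_null_false_call_fraction_below_half_percent(self):
        rows = null_phospho_ratio_rows(20000, 0.05, seed=42)
        null = fit_null_model(rows, PHOSPHO)
        calls = call_phospho_differential(rows, null, PHOSPHO)
        assert len({c.target for c in calls}) / 20000 <= 0.005


def brute_force_glyco_tmt(site_table, down=0.5, up=2.0):
    called = []
    for key, per_isoform in site_table.items():
        for isoform, clones in per_isoform.items():
            if len(clones) < 3:
                continue
            if max(clones) <= down:
                called.append((key, isoform, "down"))
            elif min(clones) >= up:
                called.append((key, isoform, "up"))
    return sorted(called)


class TestGlycoTmtRule:
    def test_consistent_down(self):
        calls = call_glyco_differential_tmt({"P1:10": {"T1": [0.4, 0.3, 0.45]}})
        assert [(c.target, c.isoform, c.direction) for c in calls] == [
            ("P1:10", "T1", "down")
        ]

    def test_one_clone_breaks_consistency(self):
        assert not call_glyco_differential_tmt(
            {"P1:10": {"T1": [0.4, 0.3, 0.6]}}
        )

    def test_fewer_than_three_clones_skipped(self):
        from glycodiff.calling import SkipCounter

        skips = SkipCounter()
        assert not call_glyco_differential_tmt(
            {"P1:10": {"T1": [0.4, 0.3]}}, skips=skips
        )
        assert skips.total == 1

    def test_exhaustive_grid_matches_brute_force(self):
        triples = list(itertools.product(GRID, repeat=3))
        site_table = {
            f"P:{i}": {"T2": list(t)} for i, t in enumerate(triples)
        }
        calls = call_glyco_differential_tmt(site_table)
        mine = sorted((c.target, c.isoform, c.direction) for c in calls)
        assert mine == brute_force_glyco_tmt(site_table)


def brute_force_selectivity(per_isoform, down=0.5, protein_quant=None, threshold=0.75):
    fully_down = [
        iso
        for iso in ISOFORMS
        if len(per_isoform.get(iso, [])) >= 3
        and all(r <= down for r in per_isoform[iso])
    ]
    if len(fully_down) >= 2:
        return ("shared", frozenset(fully_down))
    if len(fully_down) == 1:
        iso = fully_down[0]
        for other in ISOFORMS:
            if other == iso:
                continue
            clones = per_isoform.get(other, [])
            if not clones or any(r <= down for r in clones):
                return ("unchanged", None)
        quants = (protein_quant or {}).get(iso)
        if quants and sum(quants) / len(quants) <= threshold:
            return ("unchanged", None)
        return ("selective", iso)
    return ("unchanged", None)


class TestIsoformSelectivity:
    def test_selective_pattern_with_protein_control(self):
        # one isoform fully down, the others intact, protein level unchanged
        result = classify_isoform_selectivity(
            {
                "T1": [0.4, 0.3, 0.45],
                "T2": [0.8, 0.9, 1.1],
                "T3": [0.7, 1.0, 0.95],
            },
            {"T1": [0.85, 0.82, 0.85]},  # mean 0.840
        )
        assert result.status == "selective"
        assert result.isoform == "T1"

    def test_shared_between_two_isoforms(self):
        result = classify_isoform_selectivity(
            {
                "T1": [0.4, 0.3, 0.45],
                "T2": [0.2, 0.5, 0.4],
                "T3": [0.9, 1.0, 0.95],
            }
        )
        assert result.status == "shared"
        assert result.shared_isoforms == frozenset({"T1", "T2"})

    def test_all_unchanged(self):
        result = classify_isoform_selectivity(
            {iso: [1.0, 1.0, 1.0] for iso in ISOFORMS}
        )
        assert result.status == "unchanged"

    def test_protein_control_failure_downgrades(self):
        result = classify_isoform_selectivity(
            {
                "T1": [0.4, 0.3, 0.45],
                "T2": [0.8, 0.9, 1.1],
                "T3": [0.7, 1.0, 0.95],
            },
            {"T1": [0.6, 0.6, 0.6]},
        )
        assert result.status == "unchanged"

    def test_partial_data_downgrades_with_audit(self):
        result = classify_isoform_selectivity(
            {"T1": [0.4, 0.3, 0.45], "T2": [0.9, 1.0, 1.1]}
        )
        assert result.status == "unchanged"
        assert "no_data_T3" in result.audit

    def test_exhaustive_grid_matches_brute_force(self):
        others = {"T2": [1.0, 1.0, 1.0], "T3": [0.9, 1.1, 1.0]}
        for triple in itertools.product(GRID, repeat=3):
            table = {"T1": list(triple), **others}
            result = classify_isoform_selectivity(table)
            status, detail = brute_force_selectivity(table)
            assert result.status == status
            if status == "selective":
                assert result.isoform == detail


class TestProteinLevelControl:
    def test_mean_above_threshold_passes(self):
        ok, flag = protein_level_control([0.75, 0.76, 0.776])  # mean 0.762
        assert ok and "above" in flag

    def test_not_detected_passes_with_flag(self):
        ok, flag = protein_level_control(None)
        assert ok and flag == "protein_not_detected"

    def test_low_mean_fails(self):
        ok, _ = protein_level_control([0.6, 0.6, 0.6])
        assert not ok


class TestDimethylRule:
    def test_down_and_not_called(self):
        calls = call_glyco_differential_dimethyl(
            {"T1": {"P1:10": 0.3, "P1:20": 1.0}}
        )
        assert [(c.target, c.direction) for c in calls] == [("P1:10", "down")]

    def test_up_call(self):
        calls = call_glyco_differential_dimethyl({"T2": {"P1:10": 2.5}})
        assert calls[0].direction == "up"

    def test_call_count_monotone_in_down_threshold(self):
        rng = np.random.default_rng(17)
        table = {"T1": {f"P:{i}": float(r) for i, r in enumerate(rng.lognormal(-0.3, 0.5, 500))}}
        previous = None
        for down in (0.7, 0.6, 0.5, 0.4, 0.3, 0.2):
            params = CallingParams(down_threshold=down, up_threshold=math.inf)
            count = len(call_glyco_differential_dimethyl(table, params))
            if previous is not None:
                assert count <= previous
            previous = count


class TestAnova:
    def test_equal_group_means(self):
        result = anova_site_test([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert result.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_two_groups_f_equals_squared_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6).tolist(), rng.normal(1.0, 1.0, size=5).tolist()
        result = anova_site_test([a, b])
        t, _ = scipy_stats.ttest_ind(a, b, equal_var=True)
        assert result.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_sum_of_squares_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            groups = [
                rng.normal(loc=rng.normal(), size=int(rng.integers(2, 8))).tolist()
                for _ in range(int(rng.integers(2, 5)))
            ]
            result = anova_site_test(groups)
            all_values = [v for g in groups for v in g]
            grand = sum(all_values) / len(all_values)
            ss_between = sum(
                len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups
            )
            ss_within = sum(
                (v - sum(g) / len(g)) ** 2 for g in groups for v in g
            )
            df_between = len(groups) - 1
            df_within = len(all_values) - len(groups)
            f = (ss_between / df_between) / (ss_within / df_within)
            assert result.f_statistic == pytest.approx(f, rel=1e-10)

    def test_zero_within_variance_unequal_means(self):
        result = anova_site_test([[1.0, 1.0], [2.0, 2.0]])
        assert result.p_value == 0.0
        assert result.flag == "zero_within_group_variance"

    def test_all_identical_flagged(self):
        result = anova_site_test([[1.0, 1.0], [1.0, 1.0]])
        assert result.flag == "all_values_identical"

    def test_insufficient_groups(self):
        with pytest.raises(InsufficientDataError):
            anova_site_test([[1.0, 2.0]])

    def test_site_selection_at_q_cutoff(self):
        rng = np.random.default_rng(3)
        site_groups = {}
        for i in range(30):  # null sites
            site_groups[f"null:{i}"] = [
                rng.normal(size=3).tolist() for _ in range(3)
            ]
        for i in range(5):  # strongly separated sites
            site_groups[f"hit:{i}"] = [
                rng.normal(loc=5.0 * g, scale=0.1, size=3).tolist()
                for g in range(3)
            ]
        stats, selected = anova_select_sites(site_groups)
        assert set(selected) >= {f"hit:{i}" for i in range(5)}
        assert all(stats[k][2] <= 0.1 for k in selected)
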
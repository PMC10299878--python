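
import numpy as np
import pandas as pd
import pytest

from swaylab import (
    ParameterError,
    SummaryStats,
    SwayError,
    clinical_summary,
    compare_cohort,
    correlate_cohort,
    round_half_up,
    spearman,
    spearman_exact_p,
    sway_summary,
    ttest_from_samples,
    ttest_from_summary,
)


def _summary(table, key, group):
    row = table.loc[key]
    return SummaryStats(n=32, mean=row[f"{group}_mean"], sd=row[f"{group}_sd"])


@pytest.mark.parametrize("variant", ["pooled", "welch"])
@pytest.mark.parametrize(
    "score,printed",
    [("age", "0.88"), ("HY_stage", "0.02"), ("height", "0.93")],
)
def test_clinical_summary_pvalues_reproduce_printed_table(variant, score, printed):
    table = clinical_summary().set_index("score")
    res = ttest_from_summary(
        _summary(table, score, "faller"), _summary(table, score, "nonfaller"), variant
    )
    assert round_half_up(res.p, 2) == printed


def test_identical_summaries_give_null_result():
    g = SummaryStats(n=10, mean=5.0, sd=1.0)
    res = ttest_from_summary(g, g)
    assert res.t == 0.0
    assert res.p == pytest.approx(1.0)


def test_swapping_groups_negates_t_and_preserves_p():
    g1 = SummaryStats(n=12, mean=5.0, sd=1.0)
    g2 = SummaryStats(n=9, mean=4.2, sd=1.5)
    a = ttest_from_summary(g1, g2)
    b = ttest_from_summary(g2, g1)
    assert a.t == pytest.approx(-b.t, rel=1e-12)
    assert a.p == pytest.approx(b.p, rel=1e-12)


def test_zero_variance_rejected():
    g = SummaryStats(n=5, mean=1.0, sd=0.0)
    with pytest.raises(ParameterError):
        ttest_from_summary(g, g)


def test_samples_and_summary_paths_agree_exactly(rng):
    x = rng.normal(3, 1.2, 17)
    y = rng.normal(2.5, 0.8, 23)
    for variant in ("pooled", "welch"):
        from_samples = ttest_from_samples(x, y, variant)
        from_summary = ttest_from_summary(SummaryStats.of(x), SummaryStats.of(y), variant)
        assert from_samples.t == pytest.approx(from_summary.t, abs=1e-12)
        assert from_samples.df == pytest.approx(from_summary.df, abs=1e-12)
        assert from_samples.p == pytest.approx(from_summary.p, abs=1e-12)


def test_pooled_t_matches_hand_computation():
    # x=[1,2,3], y=[2,4,6]: pooled variance ((2)(1)+(2)(4))/4 = 2.5,
    # se = sqrt(2.5 * 2/3), t = -2/se
    res = ttest_from_samples([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], "pooled")
    se = (2.5 * (2.0 / 3.0)) ** 0.5
    assert res.t == pytest.approx(-2.0 / se, abs=1e-12)
    assert res.df == 4.0


def test_equal_group_sizes_pooled_and_welch_t_coincide(rng):
    x = rng.normal(0, 2, 16)
    y = rng.normal(1, 1, 16)
    pooled = ttest_from_samples(x, y, "pooled")
    welch = ttest_from_samples(x, y, "welch")
    assert pooled.t == pytest.approx(welch.t, abs=1e-12)
    assert pooled.df >= welch.df


def test_spearman_monotone_limits():
    x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
    assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)


def test_spearman_invariant_under_monotone_transforms(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(0, 1, 30)
    base = spearman(x, y)
    assert spearman(np.exp(x), y).rho == pytest.approx(base.rho, abs=1e-12)
    assert spearman(x, 3.0 * y + 7.0).rho == pytest.approx(base.rho, abs=1e-12)


def _brute_force_rho(x, y):
    """Explicit midranks, then the Pearson formula written out."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


@pytest.mark.parametrize(
    "x,y",
    [
        ([1, 2, 2, 3], [4, 4, 5, 6]),
        ([1, 1, 2, 3, 3], [2, 3, 3, 1, 5]),
        ([5, 5, 5, 1, 2, 3], [1, 2, 3, 4, 5, 6]),
        ([1, 2, 3, 4, 5, 6, 7, 8], [2, 1, 4, 3, 6, 5, 8, 7]),
    ],
)
def test_spearman_matches_brute_force_rank_oracle(x, y):
    assert spearman(x, y).rho == pytest.approx(_brute_force_rho(x, y), abs=1e-12)


def test_spearman_rejects_constant_input():
    with pytest.raises(SwayError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_exact_permutation_p_orders_like_the_approximation():
    """On small fixtures, the t-approximation ranks evidence the same way
    as exhaustive permutation."""
    fixtures = [
        ([1, 2, 3, 4, 5, 6], [2, 1, 3, 5, 4, 6]),
        ([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 1, 2]),
        ([1, 2, 3, 4, 5, 6], [3, 1, 5, 2, 6, 4]),
    ]
    approx = [spearman(x, y).p for x, y in fixtures]
    exact = [spearman_exact_p(x, y) for x, y in fixtures]
    assert np.argsort(approx).tolist() == np.argsort(exact).tolist()


def _feature_frame(subject_values):
    rows = []
    for sid, group, value in subject_values:
        rows.append(
            dict(subject_id=sid, group=group, measure="mean_velocity",
                 direction="overall", value=value)
        )
    return pd.DataFrame(rows)


def test_identical_groups_give_zero_t():
    frame = _feature_frame(
        [("a", "faller", 1.0), ("b", "faller", 2.0),
         ("c", "nonfaller", 1.0), ("d", "nonfaller", 2.0)]
    )
    comps = compare_cohort(frame)
    assert len(comps) == 1
    assert comps[0].t == 0.0
    assert comps[0].p == pytest.approx(1.0)


def test_alpha_one_flags_every_row(rng):
    frame = _feature_frame(
        [(f"s{i}", g, float(v)) for i, (g, v) in enumerate(
            [("faller", x) for x in rng.normal(0, 1, 5)]
            + [("nonfaller", x) for x in rng.normal(0, 1, 5)]
        )]
    )
    comps = compare_cohort(frame, alpha=1.0)
    assert all(c.significant for c in comps)


def test_correlation_with_self_is_one(rng):
    values = rng.normal(10, 2, 8)
    frame = _feature_frame(
        [(f"s{i}", "faller" if i < 4 else "nonfaller", float(v))
         for i, v in enumerate(values)]
    )
    clinical = pd.DataFrame(
        {"FOF": values}, index=pd.Index([f"s{i}" for i in range(8)], name="subject_id")
    )
    out = correlate_cohort(frame, clinical, ["FOF"])
    assert out.loc[0, "rho"] == pytest.approx(1.0)


def test_permuted_scores_are_mostly_uncorrelated(rng):
    n = 40
    values = rng.normal(10, 2, n)
    frame = _feature_frame(
        [(f"s{i}", "faller" if i < n // 2 else "nonfaller", float(v))
         for i, v in enumerate(values)]
    )
    clinical = pd.DataFrame(
        {"FOF": rng.permutation(values)},
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    out = correlate_cohort(frame, clinical, ["FOF"])
    assert (out["p"] > 0.05).mean() >= 0.99  # single pair here; must be null
    assert abs(out.loc[0, "rho"]) < 0.35


def test_sway_summary_table_has_all_sixteen_rows():
    table = sway_summary()
    assert len(table) == 16
    assert set(table["measure"]) == {
        "mean_velocity", "mean_distance", "mean_frequency",
        "peak_frequency", "peak_power", "sway_area",
    }
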
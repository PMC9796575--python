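"""Spearman screening, FDR control, threshold curves and the
pseudo-correlation diagnostic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from porescreen.otu import RelAbundanceTable
from porescreen.screen import (
    EnvMatrix,
    bh_fdr,
    correlated_abundance_at,
    phylum_composition,
    pseudo_correlation_diagnostic,
    screen_site,
    spearman,
    threshold_curve,
)


def enum_spearman(x, y):
    """Definition-level oracle: Pearson on mid-ranks, two-sided p by full
    enumeration of all permutations of one rank vector."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    rho = ((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy)
    perms = np.array(list(itertools.permutations(ry)))
    pc = perms - perms.mean(axis=1, keepdims=True)
    rhos = pc @ (rx - rx.mean()) / (len(rx) * sx * sy)
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), p


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestSpearman:
    def test_perfect_monotone_exact_p(self):
        res = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / 120)

    def test_hand_rank_pearson(self):
        res = spearman([1, 2, 3], [3, 1, 2])
        assert res.rho == pytest.approx(-0.5)

    def test_constant_vector_missing_with_reason(self):
        res = spearman([1, 2, 3, 4], [7, 7, 7, 7])
        assert res.missing and res.reason == "constant input"

    def test_pairwise_deletion(self):
        res = spearman([1, 2, np.nan, 4, 5], [1, 3, 9, 2, 6])
        assert res.n == 4

    def test_too_few_pairs(self):
        res = spearman([1, np.nan, 3], [1, 2, 3])
        assert res.missing and "fewer than 3" in res.reason

    def test_matches_enumeration_oracle_including_ties(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 5, n).astype(float)  # small range -> many ties
            y = rng.integers(0, 5, n).astype(float)
            rho_o, p_o = enum_spearman(x, y)
            res = spearman(x, y, method="exact")
            if np.isnan(rho_o):
                assert res.missing
            else:
                assert res.rho == pytest.approx(rho_o, abs=1e-12)
                assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_approx_agrees_with_scipy_large_n(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman(x, y, method="approx")
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.005], [0.005]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.9, 0.95], [0.95, 0.95]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_definition_never_below_p_order_invariant(self, p):
        q = bh_fdr(p)
        assert q == pytest.approx(bh_stepup(p), abs=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_fdr(np.asarray(p)[perm])
        assert sorted(q_perm) == pytest.approx(sorted(q), abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def _site_ra(values: dict, depths) -> RelAbundanceTable:
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(len(depths))])
    df = df.div(df.sum(axis=1), axis=0)
    meta = pd.DataFrame(
        {"site_id": "a", "depth_cm": depths}, index=df.index
    )
    tax = pd.Series({o: "d__B;p__Proteobacteria" for o in df}, name="lineage")
    return RelAbundanceTable(proportions=df, sample_meta=meta, taxonomy=tax)


def _env(depths, **factors) -> EnvMatrix:
    df = pd.DataFrame({"depth": depths, **factors}, index=pd.Index(depths))
    return EnvMatrix(sites={"a": df})


DEPTHS = 2.5 + 5.0 * np.arange(9)


class TestScreenSite:
    def test_planted_monotone_retained_with_rho_one(self):
        up = np.linspace(0.1, 0.5, 9)
        ra = _site_ra(
            {"up": up, "flat": np.full(9, 0.2), "rest": 0.8 - up}, DEPTHS
        )
        out = screen_site(ra, _env(DEPTHS), "depth")
        assert "up" in out.index
        assert out.loc["up", "abs_rho"] == pytest.approx(1.0)
        assert "flat" not in out.index  # constant -> missing rho, excluded

    def test_all_zero_otu_excluded(self):
        ra = _site_ra({"up": np.arange(1, 10), "zero": np.zeros(9)}, DEPTHS)
        out = screen_site(ra, _env(DEPTHS), "depth")
        assert "zero" not in out.index

    def test_p_gate_removes_noise(self):
        rng = np.random.default_rng(0)
        vals = {f"n{i}": rng.uniform(1, 2, 9) for i in range(50)}
        vals["up"] = np.arange(1.0, 10.0)
        ra = _site_ra(vals, DEPTHS)
        out = screen_site(ra, _env(DEPTHS), "depth")
        assert (out["p_value"] <= 0.05).all()
        assert out.attrs["n_tested"] == 51

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        vals = {f"n{i}": rng.uniform(1, 2, 9) for i in range(30)}
        ra = _site_ra(vals, DEPTHS)
        out = screen_site(ra, _env(DEPTHS), "depth")
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_misaligned_depths_error(self):
        ra = _site_ra({"up": np.arange(1, 10)}, DEPTHS)
        env = _env(DEPTHS + 100.0)
        with pytest.raises(ValueError, match="depths"):
            screen_site(ra, env, "depth")

    def test_few_complete_pairs_skips_with_warning(self):
        factor = np.array([1.0, 2.0, 3.0] + [np.nan] * 6)
        ra = _site_ra({"up": np.arange(1, 10)}, DEPTHS)
        with pytest.warns(UserWarning, match="skipped"):
            out = screen_site(ra, _env(DEPTHS, broken=factor), "broken")
        assert out.empty and out.attrs["skipped"]

    def test_null_gate_admits_about_five_percent(self):
        """Exact permutation p-values keep the p<=0.05 gate calibrated:
        independent OTUs pass at most ~5% of the time (plus discreteness)."""
        rng = np.random.default_rng(99)
        vals = {f"n{i}": rng.uniform(1, 2, 9) for i in range(800)}
        ra = _site_ra(vals, DEPTHS)
        out = screen_site(ra, _env(DEPTHS), "depth")
        rate = len(out) / out.attrs["n_tested"]
        assert rate <= 0.07


def _entries(rows) -> pd.DataFrame:
    df = pd.DataFrame(
        rows, columns=["otu_id", "abs_rho", "mean_ra", "p_value", "fdr_pass"]
    ).set_index("otu_id")
    df["rho"] = df["abs_rho"]
    df["q_value"] = df["p_value"]
    return df


class TestThresholdCurve:
    def test_empty_entries_zero_curve(self):
        curve = threshold_curve(_entries([]))
        assert (curve.yra == 0).all()

    def test_single_entry_evaluation(self):
        curve = threshold_curve(_entries([("a", 0.9, 0.2, 0.01, True)]))
        assert curve.at(0.8) == pytest.approx(0.2)
        assert curve.at(0.95) == 0.0

    def test_zero_threshold_totals_retained_abundance(self):
        e = _entries(
            [("a", 0.9, 0.2, 0.01, True), ("b", 0.5, 0.3, 0.02, True)]
        )
        assert threshold_curve(e).at(0.0) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 0.05)),
            min_size=0,
            max_size=50,
        )
    )
    def test_curve_non_increasing(self, pairs):
        e = _entries(
            [(f"o{i}", r, a, 0.01, True) for i, (r, a) in enumerate(pairs)]
        )
        curve = threshold_curve(e)
        assert (np.diff(curve.yra) <= 1e-12).all()
        assert ((curve.yra >= 0) & (curve.yra <= 1 + 1e-9)).all()


class TestCorrelatedAbundance:
    def test_strictly_larger_than_threshold(self):
        e = _entries([("a", 0.8, 0.4, 0.01, True)])
        assert correlated_abundance_at(e, t=0.8) == 0.0

    def test_direct_evaluation(self):
        e = _entries(
            [("a", 0.85, 0.1, 0.01, True), ("b", 0.7, 0.3, 0.01, True)]
        )
        assert correlated_abundance_at(e, t=0.8) == pytest.approx(0.1)

    def test_empty(self):
        assert correlated_abundance_at(_entries([]), t=0.8) == 0.0

    def test_fdr_failures_excluded(self):
        e = _entries([("a", 0.9, 0.1, 0.01, False)])
        assert correlated_abundance_at(e, t=0.8) == 0.0


class TestPhylumComposition:
    def _tax(self):
        return pd.Series(
            {
                "a": "d__B;p__Proteobacteria",
                "b": "d__B;p__Chloroflexi",
                "c": "d__B;p__Proteobacteria",
            },
            name="lineage",
        )

    def test_single_phylum_share_one(self):
        e = _entries([("a", 0.9, 0.2, 0.01, True), ("c", 0.85, 0.1, 0.01, True)])
        comp = phylum_composition(e, self._tax())
        assert comp.to_dict() == pytest.approx({"Proteobacteria": 1.0})

    def test_normalized_shares(self):
        e = _entries([("a", 0.9, 0.3, 0.01, True), ("b", 0.85, 0.1, 0.01, True)])
        comp = phylum_composition(e, self._tax())
        assert comp["Proteobacteria"] == pytest.approx(0.75)
        assert comp["Chloroflexi"] == pytest.approx(0.25)

    def test_empty_set_empty_composition(self):
        comp = phylum_composition(_entries([]), self._tax())
        assert comp.empty and not comp.isna().any()


class TestPseudoDiagnostic:
    def test_identity_factor_is_pseudo(self):
        """A factor equal to depth itself: rho 1, overlap 1, flagged."""
        ra = _site_ra({"up": np.arange(1, 10), "down": np.arange(10, 1, -1)}, DEPTHS)
        env = _env(DEPTHS, clone=DEPTHS.astype(float))
        d_e = screen_site(ra, env, "depth")
        f_e = screen_site(ra, env, "clone")
        diag = pseudo_correlation_diagnostic(f_e, d_e, env, "a", "clone")
        assert diag.rho_factor_depth == pytest.approx(1.0)
        assert diag.overlap == pytest.approx(1.0)
        assert diag.verdict == "likely-pseudo"

    def test_independent_factor_no_signal(self):
        rng = np.random.default_rng(3)
        vals = {f"n{i}": rng.uniform(1, 2, 9) for i in range(20)}
        vals["up"] = np.arange(1.0, 10.0) ** 2
        ra = _site_ra(vals, DEPTHS)
        noise = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.5])
        env = _env(DEPTHS, indep=noise)
        d_e = screen_site(ra, env, "depth")
        f_e = screen_site(ra, env, "indep")
        diag = pseudo_correlation_diagnostic(f_e, d_e, env, "a", "indep")
        assert diag.verdict == "no-signal"

    def test_no_depth_gradient_verdict(self):
        rng = np.random.default_rng(4)
        vals = {f"n{i}": rng.uniform(1, 2, 9) for i in range(20)}
        ra = _site_ra(vals, DEPTHS)
        env = _env(DEPTHS, f=np.arange(9.0))
        d_e = screen_site(ra, env, "depth")
        f_e = screen_site(ra, env, "f")
        diag = pseudo_correlation_diagnostic(f_e, d_e, env, "a", "f")
        assert diag.verdict == "no-gradient"
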
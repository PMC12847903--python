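"""Cohort statistics: contrast, balance, survival, volcano, subtypes."""

import itertools
import math

import numpy as np
import pytest

from sigscore import (CohortRecord, InsufficientDataError,
                      UndefinedStatisticError, assign_subtype,
                      classification_contrast, clr_transform,
                      median_split_survival, read_clinical, sig_count_balance,
                      survival_correlation, volcano_differential,
                      write_clinical)
from sigscore.cohort import balance_histogram
from sigscore.errors import DegenerateSplitError
from sigscore.scoring import SigScoreResult
from tests.conftest import make_table


def result(sample_id="s", n1=0, n2=0, score=0.5, primary="GRAY",
           final="SIG1+", gray="akk_absent", akk=0.0):
    return SigScoreResult(sample_id=sample_id, n_sig1=n1, n_sig2=n2,
                          score=score, primary_label=primary,
                          final_label=final, gray_resolution=gray,
                          akk_abundance=akk)


def labelled(sample_id, primary):
    final = primary if primary != "GRAY" else "SIG1+"
    return result(sample_id=sample_id, primary=primary, final=final)


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration: sum the
    probabilities of all tables with the same margins that are no more
    probable than the observed one."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def log_prob(x):
        lg = math.lgamma
        y, z, w = col1 - x, row1 - x, row2 - (col1 - x)
        if min(x, y, z, w) < 0:
            return None
        return (lg(row1 + 1) + lg(row2 + 1) + lg(col1 + 1)
                + lg(n - col1 + 1) - lg(n + 1)
                - lg(x + 1) - lg(y + 1) - lg(z + 1) - lg(w + 1))

    obs = log_prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        lp = log_prob(x)
        if lp is not None and lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


class TestClassificationContrast:
    def test_identical_proportions_show_no_association(self):
        healthy = [labelled(f"h{i}", p)
                   for i, p in enumerate(["SIG1+"] * 2 + ["SIG2+"] * 8)]
        cancer = [labelled(f"c{i}", p)
                  for i, p in enumerate(["SIG1+"] * 2 + ["SIG2+"] * 8)]
        res = classification_contrast(healthy, cancer)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_table_matches_hypergeometric_oracle(self):
        healthy = [labelled(f"h{i}", "SIG2+") for i in range(8)]
        healthy += [labelled("h8", "SIG1+"), labelled("h9", "GRAY")]
        cancer = [labelled(f"c{i}", "SIG2+") for i in range(2)]
        cancer += [labelled(f"c{i+2}", "SIG1+") for i in range(8)]
        res = classification_contrast(healthy, cancer)
        # 2x2 is (SIG2+, not): healthy (8, 2), cancer (2, 8)
        assert res.table_2x2.to_numpy().tolist() == [[8, 2], [2, 8]]
        assert res.p_value == pytest.approx(fisher_2x2_oracle(8, 2, 2, 8),
                                            rel=1e-9)

    def test_fisher_matches_oracle_on_many_margins(self):
        # all 2x2 tables with margins <= 12 on a coarse grid
        from scipy.stats import fisher_exact
        for a, b, c, d in itertools.product(range(0, 13, 3), repeat=4):
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_2x2_oracle(a, b, c, d),
                                      rel=1e-8, abs=1e-12)

    def test_zero_cell_gives_finite_odds_ratio(self):
        healthy = [labelled(f"h{i}", "SIG2+") for i in range(10)]
        cancer = [labelled(f"c{i}", "SIG1+") for i in range(10)]
        res = classification_contrast(healthy, cancer)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            classification_contrast([], [labelled("c0", "SIG1+")])

    def test_exact_2x3_variant(self):
        healthy = [labelled(f"h{i}", p) for i, p in
                   enumerate(["SIG1+"] * 1 + ["GRAY"] * 3 + ["SIG2+"] * 10)]
        cancer = [labelled(f"c{i}", p) for i, p in
                  enumerate(["SIG1+"] * 7 + ["GRAY"] * 5 + ["SIG2+"] * 2)]
        res = classification_contrast(healthy, cancer, exact_2x3=True,
                                      seed=3)
        assert 0.0 < res.p_value_2x3 < 0.05


class TestSigBalance:
    def test_all_zero_cohort(self):
        res = sig_count_balance([result(f"s{i}") for i in range(4)])
        assert (res["balance"] == 0).all()

    def test_convention_sig1_minus_sig2(self):
        res = sig_count_balance([result("s0", n1=0, n2=45)])
        assert res["balance"].tolist() == [-45]

    def test_binned_counts_match_enumeration(self):
        counts = [(3, 1), (5, 1), (5, 3), (0, 4)]
        res = sig_count_balance([result(f"s{i}", n1=a, n2=b)
                                 for i, (a, b) in enumerate(counts)])
        bins = balance_histogram(res)
        expected = {2: 2, 4: 1, -4: 1}  # hand enumeration of n1 - n2
        got = dict(zip(bins["balance"], bins["count"]))
        assert {k: v for k, v in got.items() if v} == expected


def clinical_record(sid, t, event=True, group="cancer", pfs=None,
                    pfs_event=None):
    return CohortRecord(sample_id=sid, group=group, os_months=t,
                        os_event=event, pfs_months=pfs, pfs_event=pfs_event)


class TestSurvivalCorrelation:
    def test_perfect_inverse_ranking(self):
        results = [result(f"s{i}", n1=i) for i in range(10)]
        clin = [clinical_record(f"s{i}", 100.0 - i) for i in range(10)]
        corr = survival_correlation(results, clin)
        assert corr.rho == pytest.approx(-1.0)
        assert corr.n == 10

    def test_null_simulation_is_uncorrelated(self):
        rng = np.random.default_rng(77)
        n1 = rng.integers(0, 20, size=500)
        times = rng.exponential(20.0, size=500)
        results = [result(f"s{i}", n1=int(n1[i])) for i in range(500)]
        clin = [clinical_record(f"s{i}", float(times[i])) for i in range(500)]
        corr = survival_correlation(results, clin)
        assert abs(corr.rho) < 0.1
        assert corr.p_value > 0.01

    def test_constant_counts_rejected(self):
        results = [result(f"s{i}", n1=5) for i in range(5)]
        clin = [clinical_record(f"s{i}", 10.0 + i) for i in range(5)]
        with pytest.raises(UndefinedStatisticError):
            survival_correlation(results, clin)

    def test_too_few_pairs_rejected(self):
        results = [result("s0", n1=1), result("s1", n1=2)]
        clin = [clinical_record("s0", 5.0), clinical_record("s1", 4.0)]
        with pytest.raises(InsufficientDataError):
            survival_correlation(results, clin)

    def test_events_only_variant_filters(self):
        results = [result(f"s{i}", n1=i) for i in range(6)]
        clin = [clinical_record(f"s{i}", 50.0 - i, event=(i % 2 == 0))
                for i in range(6)]
        corr = survival_correlation(results, clin, events_only=True)
        assert corr.n == 3


class TestMedianSplitSurvival:
    def test_separated_point_masses(self):
        results = [result(f"a{i}", n1=15) for i in range(20)]
        results += [result(f"b{i}", n1=2) for i in range(20)]
        clin = [clinical_record(f"a{i}", 1.0) for i in range(20)]
        clin += [clinical_record(f"b{i}", 2.0) for i in range(20)]
        res = median_split_survival(results, clin)
        assert res.median_high == pytest.approx(1.0)
        assert res.median_low == pytest.approx(2.0)
        assert res.logrank_p < 1e-6
        for km in (res.km_high, res.km_low):
            surv = km["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()  # non-increasing
            assert ((surv >= 0) & (surv <= 1)).all()

    def test_null_exponential_arms_similar(self):
        rng = np.random.default_rng(5)
        results = [result(f"s{i}", n1=int(rng.integers(0, 20)))
                   for i in range(200)]
        clin = [clinical_record(f"s{i}", float(rng.exponential(20.0)))
                for i in range(200)]
        res = median_split_survival(results, clin)
        assert res.logrank_p > 0.001  # no planted effect

    def test_fully_censored_cohort_rejected(self):
        results = [result(f"s{i}", n1=i) for i in range(10)]
        clin = [clinical_record(f"s{i}", 10.0, event=False)
                for i in range(10)]
        with pytest.raises(UndefinedStatisticError):
            median_split_survival(results, clin)

    def test_degenerate_split_rejected(self):
        results = [result(f"s{i}", n1=5) for i in range(10)]
        clin = [clinical_record(f"s{i}", 10.0 + i) for i in range(10)]
        with pytest.raises(DegenerateSplitError):
            median_split_survival(results, clin)  # all samples in one arm

    def test_pfs_endpoint(self):
        results = [result(f"s{i}", n1=i) for i in range(10)]
        clin = [clinical_record(f"s{i}", 20.0, event=False,
                                pfs=10.0 - 0.5 * i, pfs_event=True)
                for i in range(10)]
        res = median_split_survival(results, clin, endpoint="pfs")
        assert res.endpoint == "pfs"
        assert res.median_high < res.median_low


class TestVolcanoDifferential:
    def _clr(self, values, names):
        return clr_transform(make_table(values, names))

    def test_identical_groups_show_nothing(self):
        rng = np.random.default_rng(3)
        block = rng.uniform(0.5, 5.0, size=(5, 4))
        values = np.vstack([block, block])  # high group copies the low group
        names = [f"taxon {i}" for i in range(4)]
        clr = self._clr(values, names)
        results = [result(f"s{i}", n1=(10 if i < 5 else 0))
                   for i in range(10)]
        df = volcano_differential(clr, results)
        assert np.allclose(df["effect"], 0.0)
        assert (df["q_value"] > 0.5).all()

    def test_planted_shift_is_top_hit(self):
        rng = np.random.default_rng(21)
        n = 100
        values = rng.lognormal(-1.0, 0.5, size=(2 * n, 6))
        values[:n, 0] *= math.e ** 2  # +2 CLR units in the high group
        values = np.clip(values, 0, 50)
        names = [f"taxon {i}" for i in range(6)]
        clr = self._clr(values, names)
        results = [result(f"s{i}", n1=(12 if i < n else 3))
                   for i in range(2 * n)]
        df = volcano_differential(clr, results)
        top = df.iloc[df["effect"].abs().idxmax()]
        assert top["taxon"] == "taxon 0"
        assert top["q_value"] < 0.05

    def test_bh_matches_independent_step_up(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(-1.0, 1.0, size=(30, 10))
        names = [f"taxon {i}" for i in range(10)]
        clr = self._clr(values, names)
        results = [result(f"s{i}", n1=int(i < 15) * 10) for i in range(30)]
        df = volcano_differential(clr, results)
        p = df["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for pos in range(m - 1, -1, -1):
            prev = min(prev, p[order[pos]] * m / (pos + 1))
            q[order[pos]] = prev
        assert np.allclose(df["q_value"].to_numpy(), q)
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()

    def test_small_group_rejected(self):
        rng = np.random.default_rng(0)
        clr = self._clr(rng.uniform(0.5, 2.0, (4, 3)),
                        ["a x", "b x", "c x"])
        results = [result(f"s{i}", n1=i) for i in range(4)]
        with pytest.raises(InsufficientDataError):
            volcano_differential(clr, results)


class TestSubtypes:
    def test_eubiotic_sample_unclassified(self, catalog):
        r = result("s0", n1=0, n2=40, score=0.94, primary="SIG2+",
                   final="SIG2+", gray="not_gray")
        st = assign_subtype(r, set(), catalog)
        assert st.subtype == "unclassified"

    def test_collapse_with_gut_anaerobes_is_type2(self, catalog):
        detected = {t.canonical for t in catalog.sig1_gut[:6]}
        detected |= {t.canonical for t in catalog.sig2[:3]}
        r = result("s0", n1=6, n2=3, score=0.2, primary="SIG1+",
                   final="SIG1+", gray="not_gray")
        st = assign_subtype(r, detected, catalog)
        assert st.sig2_retention == pytest.approx(3 / 45)
        assert st.oral_fraction == 0.0
        assert st.subtype == "type2"

    def test_modest_loss_with_oral_spillover_is_type1(self, catalog):
        detected = {t.canonical for t in catalog.sig1_oral[:4]}
        detected |= {t.canonical for t in catalog.sig1_gut[:2]}
        detected |= {t.canonical for t in catalog.sig2[:25]}
        r = result("s0", n1=6, n2=25, score=0.5, primary="SIG1+",
                   final="SIG1+", gray="not_gray")
        st = assign_subtype(r, detected, catalog)
        assert st.sig2_retention == pytest.approx(25 / 45)
        assert st.oral_fraction == pytest.approx(4 / 6)
        assert st.subtype == "type1"

    def test_mixed_profile_unclassified(self, catalog):
        detected = {t.canonical for t in catalog.sig1_gut[:6]}
        detected |= {t.canonical for t in catalog.sig2[:20]}
        r = result("s0", n1=6, n2=20, score=0.45, primary="SIG1+",
                   final="SIG1+", gray="not_gray")
        st = assign_subtype(r, detected, catalog)
        assert st.subtype == "unclassified"

    def test_deterministic_in_inputs(self, catalog):
        detected = {t.canonical for t in catalog.sig1_oral[:4]}
        r = result("s0", n1=4, n2=2, score=0.3, primary="SIG1+",
                   final="SIG1+", gray="not_gray")
        assert (assign_subtype(r, detected, catalog)
                == assign_subtype(r, detected, catalog))


class TestClinicalIO:
    def test_round_trip(self, tmp_path):
        records = [
            CohortRecord("s0", "healthy"),
            CohortRecord("s1", "cancer", cancer_type="NSCLC", os_months=12.5,
                         os_event=True, pfs_months=6.0, pfs_event=False),
        ]
        path = tmp_path / "clinical.csv"
        write_clinical(records, path)
        assert read_clinical(path) == records

    def test_event_flag_required_with_time(self):
        with pytest.raises(Exception):
            CohortRecord("s0", "cancer", os_months=5.0)
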
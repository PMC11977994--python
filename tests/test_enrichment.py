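import math

import numpy as np
import pandas as pd
import pytest

from sefx import (
    ContingencyTable2x2,
    DrugRecord,
    GeneratorConfig,
    GeneticAssociation,
    SideEffectRecord,
    by_source,
    cmh_across_areas,
    generate,
    logit_conditional,
    logit_interaction,
    pleiotropy_check,
    primary_enrichment,
    severity_specificity_regression,
    sweep_assoc_threshold,
    sweep_indic_threshold,
    target_se_enrichment,
)
from sefx.enrichment import _poly_contrasts
from sefx.filters import FilterConfig, flag_evidence
from sefx.simulate import build_pipeline_universe, replicate_enrichment, recovery_report
from sefx.tables import PairUniverse, build_universe

from conftest import identity_similarity


class TestPrimary:
    def test_recovers_planted_or(self, small_dataset, retained_universe):
        r = primary_enrichment(retained_universe)
        # planted conditional OR is 2; a single draw should land well
        # within a factor-of-1.5 band
        assert 2.0 / 1.5 < r.or_estimate < 2.0 * 1.5
        assert r.ci_low < r.or_estimate < r.ci_high

    def test_null_covers_one(self):
        ds = generate(GeneratorConfig(seed=21, beta_evidence=0.0))
        results = replicate_enrichment(ds, 60, seed=5)
        cover = np.mean([r.ci_low <= 1.0 <= r.ci_high for r in results])
        assert cover >= 0.85

    def test_all_evidence_margin_error(self, retained_universe):
        uni = retained_universe.subset(retained_universe.df["has_evidence"].to_numpy())
        with pytest.raises(ValueError, match="margin"):
            primary_enrichment(uni)


class TestSweeps:
    def test_evidence_count_monotone_in_theta(self, small_universe):
        grid = [0.0, 0.25, 0.5, 0.75, 0.9, 1.0]
        out = sweep_assoc_threshold(small_universe, grid)
        counts = out["n_evidence_pairs"].to_numpy()
        assert np.all(np.diff(counts) <= 0)

    def test_degenerate_zero_threshold(self, small_universe):
        out = sweep_assoc_threshold(small_universe, [0.0])
        # at theta 0 every pair whose drug has any qualified association
        # carries evidence
        df = small_universe.df
        keep = df["insight"] & ~df["excluded_similar_indication"]
        assert out["n_evidence_pairs"].iloc[0] == int(
            (df["best_assoc_sim_qualified"][keep] >= 0).sum()
        )

    def test_retained_monotone_in_theta_indic(self, small_universe):
        grid = [0.5, 0.75, 0.9, 1.0]
        out = sweep_indic_threshold(small_universe, grid)
        retained = out["n_retained"].to_numpy()
        assert np.all(np.diff(retained) >= 0)

    def test_indic_sweep_counts_match_recount(self, small_universe):
        out = sweep_indic_threshold(small_universe, [0.8])
        df = small_universe.df
        keep = df["insight"] & (df["best_indic_sim"] < 0.8)
        assert out["n_retained"].iloc[0] == int(keep.sum())

    def test_two_regime_inflection(self):
        """With the effect planted at sim >= 0.9 only, the sweep OR is
        larger at high thresholds than at low ones."""
        ds = generate(GeneratorConfig(seed=31, beta_evidence=math.log(3)))
        uni, _ = build_pipeline_universe(ds)
        flagged = flag_evidence(uni)
        out = sweep_assoc_threshold(flagged, [0.3, 0.9])
        lo, hi = out["or_estimate"].to_numpy()
        assert hi > lo


class TestBySource:
    def test_unknown_source_rejected(self, retained_universe):
        with pytest.raises(ValueError, match="unknown"):
            by_source(retained_universe, "GTEx")

    def test_single_source_dataset_other_sources_empty(self):
        ds = generate(
            GeneratorConfig(seed=41, source_mix=(("OMIM", 1.0), ("OTG", 0.0),
                                                 ("PICCOLO", 0.0), ("Genebass", 0.0),
                                                 ("IntOGen", 0.0)))
        )
        uni, _ = build_pipeline_universe(ds)
        with pytest.raises(ValueError, match="margin"):
            by_source(uni, "OTG")  # no OTG associations -> empty evidence margin

    def test_union_evidence_contains_each_source(self, retained_universe):
        uni = retained_universe
        union = uni.df["has_evidence"].to_numpy()
        for source in ("OMIM", "OTG"):
            sub = PairUniverse(
                uni.df, list(uni.drugs.values()), uni.se_records,
                [a for a in uni.assocs if a.source == source], uni.sim,
            )
            qualified = sub.drug_traits(qualified_theta_indic=0.9)
            ev = sub.best_sim_per_drug(qualified) >= 0.9
            assert not np.any(ev & ~union)


class TestLogits:
    def test_constant_covariate_inestimable(self, retained_universe):
        with pytest.raises(ValueError, match="inestimable"):
            logit_interaction(retained_universe, np.ones(len(retained_universe)))

    def test_interaction_coefficient_recovered(self):
        """A planted interaction between evidence and a binary covariate is
        recovered within 2 SE."""
        rng = np.random.default_rng(8)
        n = 40000
        ev = rng.random(n) < 0.3
        cov = (rng.random(n) < 0.5).astype(float)
        beta_int = 0.7
        logit = -2.5 + 0.5 * ev + 0.2 * cov + beta_int * ev * cov
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame(
            {"drug_id": "D", "se_term": [f"S{i}" for i in range(n)],
             "observed": y, "has_evidence": ev}
        )
        uni = PairUniverse(df, [DrugRecord("D", frozenset("G"), frozenset("I"))],
                           [], [], identity_similarity(["I"]))
        out = logit_interaction(uni, cov).set_index("term")
        est = out.loc["evidence:covariate", "estimate"]
        se = out.loc["evidence:covariate", "se"]
        assert abs(est - beta_int) < 2 * se

    def test_null_interaction_p_uniformish(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(40):
            n = 4000
            ev = rng.random(n) < 0.3
            cov = rng.normal(size=n)
            y = rng.random(n) < 1 / (1 + np.exp(2.0 - 0.5 * ev))
            df = pd.DataFrame(
                {"drug_id": "D", "se_term": [f"S{i}" for i in range(n)],
                 "observed": y, "has_evidence": ev}
            )
            uni = PairUniverse(df, [DrugRecord("D", frozenset("G"), frozenset("I"))],
                               [], [], identity_similarity(["I"]))
            out = logit_interaction(uni, cov).set_index("term")
            ps.append(out.loc["evidence:covariate", "p"])
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform under the null

    def test_conditional_slope_recovered_numeric_and_ordinal(self):
        rng = np.random.default_rng(10)
        n = 20000
        rank = rng.integers(1, 6, size=n)
        slope = 0.4
        ev = rng.random(n) < 1 / (1 + np.exp(-(-2.0 + slope * rank)))
        df = pd.DataFrame({"has_evidence": ev, "freq_word": rank})
        out = logit_conditional(df, "freq_word", treatment="numeric").set_index("term")
        est, se = out.loc["freq_word", ["estimate", "se"]]
        assert abs(est - slope) < 2 * se
        out2 = logit_conditional(df, "freq_word", treatment="ordinal")
        assert {"freq_word.linear", "freq_word.quadratic"} <= set(out2["term"])
        lin_row = out2.set_index("term").loc["freq_word.linear"]
        assert lin_row["p"] < 1e-6  # strong linear trend detected

    def test_word_vocabulary_mapping(self):
        df = pd.DataFrame(
            {"has_evidence": [True, False, True, False] * 10,
             "freq_word": ["rare", "common", "common", "rare"] * 10}
        )
        out = logit_conditional(df, "freq_word", word_order=["rare", "common"])
        assert len(out) == 2  # intercept + linear term
        with pytest.raises(ValueError, match="vocabulary"):
            logit_conditional(df, "freq_word", word_order=["rare"])

    def test_poly_contrasts_orthonormal(self):
        codes = _poly_contrasts(np.array([1, 2, 3, 4, 1, 2]), degree=3)
        lev = _poly_contrasts(np.array([1, 2, 3, 4]), degree=3)
        np.testing.assert_allclose(lev.T @ lev, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(lev.sum(axis=0), 0, atol=1e-10)


class TestStratified:
    def test_identical_strata_homogeneous(self):
        t = ContingencyTable2x2(30, 70, 20, 80)
        res = cmh_across_areas({"A": t, "B": t, "C": t})
        assert res.heterogeneity_p > 0.9
        # pooled MH OR of identical tables equals the single-table MH OR
        single = (30 * 80) / (70 * 20)
        assert res.common_or == pytest.approx(single)

    def test_heterogeneity_detected_and_matches_oracle(self):
        # strata with ORs 1 and 8 at n = 200 each
        t1 = ContingencyTable2x2(25, 75, 25, 75)
        t2 = ContingencyTable2x2(56, 44, 14, 86)
        res = cmh_across_areas({"A": t1, "B": t2})
        assert res.heterogeneity_p < 0.001
        # oracle: statsmodels is the implementation, so cross-check the
        # MH pooled OR against the hand formula sum(ad/n)/sum(bc/n)
        num = (25 * 75) / 200 + (56 * 86) / 200
        den = (75 * 25) / 200 + (44 * 14) / 200
        assert res.common_or == pytest.approx(num / den)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError, match="strata"):
            cmh_across_areas({"A": ContingencyTable2x2(5, 5, 5, 5)})


class TestTargetSE:
    def make_universe(self, drugs, observed_pairs):
        terms = sorted({t for _, t in observed_pairs} | {"IND"})
        ses = [SideEffectRecord(d, t) for d, t in observed_pairs]
        return build_universe(drugs, ses, identity_similarity(terms), [])

    def test_single_drug_target_untestable(self):
        drugs = [
            DrugRecord("D0", frozenset({"G1"}), frozenset({"IND"})),
            DrugRecord("D1", frozenset({"G2"}), frozenset({"IND"})),
            DrugRecord("D2", frozenset({"G2"}), frozenset({"IND"})),
        ]
        uni = self.make_universe(drugs, [("D0", "S1"), ("D1", "S1")])
        table, untestable = target_se_enrichment(uni)
        assert "G1" in untestable
        assert set(table["target"]) == {"G2"}

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        # step-up by hand at q = 0.05, m = 4: thresholds k/m*q are
        # 0.0125, 0.025, 0.0375, 0.05; p_(3) = 0.04 > 0.0375, so the
        # largest passing k is 2 and exactly the first two are rejected
        rej, adj, _, _ = multipletests([0.01, 0.02, 0.04, 0.9], method="fdr_bh")
        assert list(rej) == [True, True, False, False]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.05333333, 0.9], atol=1e-8)

    def test_global_null_discovery_proportion(self):
        """Under beta = gamma = 0 the BH screen discovers (almost) nothing."""
        rates = []
        for seed in (51, 52, 53):
            ds = generate(
                GeneratorConfig(seed=seed, beta_evidence=0.0, gamma_indic=0.0,
                                n_terms=150, n_genes=60, n_drugs=60)
            )
            uni, _ = build_pipeline_universe(ds)
            table, _ = target_se_enrichment(uni)
            rates.append(table["enriched"].mean())
        assert np.mean(rates) <= 0.07


class TestSmallChecks:
    def test_pleiotropy_identical_vectors(self):
        drugs = [DrugRecord(f"D{i}", frozenset({f"G{i}"}), frozenset({"I"}))
                 for i in range(5)]
        ses, assocs = [], []
        for i in range(5):
            for j in range(i + 1):
                ses.append(SideEffectRecord(f"D{i}", f"S{j}"))
                assocs.append(GeneticAssociation(f"G{i}", f"T{j}", "OMIM"))
        terms = [f"S{j}" for j in range(5)] + [f"T{j}" for j in range(5)] + ["I"]
        uni = build_universe(drugs, ses, identity_similarity(terms), assocs)
        r, p = pleiotropy_check(uni)
        assert r == pytest.approx(1.0)

    def test_pleiotropy_near_zero_when_independent(self, retained_universe):
        # the generator assigns targets and associations independently of
        # the observation process beyond the planted similarity effect
        r, _ = pleiotropy_check(retained_universe)
        assert abs(r) < 0.35

    def test_pleiotropy_zero_variance_rejected(self):
        drugs = [DrugRecord(f"D{i}", frozenset({"G"}), frozenset({"I"})) for i in range(3)]
        ses = [SideEffectRecord(f"D{i}", "S0") for i in range(3)]
        uni = build_universe(drugs, ses, identity_similarity(["S0", "I"]), [])
        with pytest.raises(ValueError, match="variance"):
            pleiotropy_check(uni)

    def test_severity_regression_closed_form(self):
        # four hand points: log n = [log 8, log 4, log 2, log 1], sev = 1..4
        df = pd.DataFrame({"n_drugs": [8, 4, 2, 1], "severity": [1, 2, 3, 4]})
        slope, p = severity_specificity_regression(df)
        assert slope == pytest.approx(-math.log(2))
        assert p < 0.01

    def test_severity_regression_flat(self):
        df = pd.DataFrame({"n_drugs": [5, 5, 5, 5], "severity": [1, 2, 3, 4]})
        slope, _ = severity_specificity_regression(df)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_severity_regression_degenerate(self):
        df = pd.DataFrame({"n_drugs": [5, 6], "severity": [1, 2]})
        with pytest.raises(ValueError, match=">= 3"):
            severity_specificity_regression(df)
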
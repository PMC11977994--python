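"""Enrichment statistics for genetic evidence among observed side effects.

The primary metric is the odds ratio from a Fisher exact test on the
2x2 table of pairs observed / unobserved against pairs with / without
genetic evidence, computed on the filtered universe.  Around it sit the
sensitivity sweeps over the two similarity thresholds, per-source
enrichment, binomial logit models for modifiers, the stratified
(Mantel-Haenszel / Breslow-Day) analysis across disease areas, the per
target-SE Fisher screen with Benjamini-Hochberg control, and two small
regression checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from ._fisher import fisher_batch
from .filters import FilterConfig
from .tables import PairUniverse, SOURCES


class SeparationError(RuntimeError):
    """Complete separation: an unpenalized logit fit is refused."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a observed-with-evidence, b observed-without,
    c unobserved-with, d unobserved-without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @classmethod
    def from_flags(cls, observed: np.ndarray, evidence: np.ndarray) -> "ContingencyTable2x2":
        observed = np.asarray(observed, dtype=bool)
        evidence = np.asarray(evidence, dtype=bool)
        return cls(
            a=int((observed & evidence).sum()),
            b=int((observed & ~evidence).sum()),
            c=int((~observed & evidence).sum()),
            d=int((~observed & ~evidence).sum()),
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher exact enrichment summary for one 2x2 table.

    ``or_estimate`` is the conditional MLE (as reported by R's
    fisher.test); ``or_sample`` the plain cross-product ratio; the CI is
    the exact interval from conditional tail inversion.  ``n_assoc`` is
    the number of evidence-bearing pairs and ``n_assoc_obs`` how many of
    those are observed (the "assoc/obs" fraction of forest plots).
    """

    or_estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_assoc_obs: int
    n_assoc: int
    or_sample: float
    table: ContingencyTable2x2

    @property
    def ppv(self) -> float:
        return self.n_assoc_obs / self.n_assoc if self.n_assoc else float("nan")


def fisher_or(t: ContingencyTable2x2, alpha: float = 0.05) -> EnrichmentResult:
    """Two-sided Fisher exact test with conditional-MLE OR and exact CI."""
    res = fisher_batch([t.a], [t.b], [t.c], [t.d], alpha=alpha)
    return EnrichmentResult(
        or_estimate=float(res["or_cmle"][0]),
        ci_low=float(res["ci_low"][0]),
        ci_high=float(res["ci_high"][0]),
        p=float(res["p"][0]),
        n_assoc_obs=t.a,
        n_assoc=t.a + t.c,
        or_sample=float(res["or_sample"][0]),
        table=t,
    )


def primary_enrichment(universe: PairUniverse) -> EnrichmentResult:
    """Fisher enrichment of evidence among observed pairs.

    Expects flags populated (and filters applied by the caller)."""
    df = universe.df
    t = ContingencyTable2x2.from_flags(df["observed"], df["has_evidence"])
    return fisher_or(t)


def _sweep(universe: PairUniverse, grid, vary: str) -> pd.DataFrame:
    df = universe.df
    rows = []
    for theta in grid:
        if not (0.0 <= theta <= 1.01):
            raise ValueError("sweep grid must lie within [0, 1]")
        if vary == "assoc":
            evidence = df["best_assoc_sim_qualified"] >= theta
            keep = ~df["excluded_similar_indication"]
        else:
            # varying the indication threshold changes both the removal
            # set and which associations are disqualified
            qualified = universe.drug_traits(qualified_theta_indic=theta)
            evidence = universe.best_sim_per_drug(qualified) >= 0.9
            keep = ~(df["best_indic_sim"] >= theta)
        keep = keep & df["insight"] if "insight" in df.columns else keep
        obs_kept = df["observed"][keep].to_numpy()
        ev_kept = np.asarray(evidence)[keep]
        row = {
            "theta": float(theta),
            "n_retained": int(keep.sum()),
            "n_evidence_pairs": int(ev_kept.sum()),
            "or_estimate": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "n_assoc_obs": int((obs_kept & ev_kept).sum()),
            "n_assoc": int(ev_kept.sum()),
        }
        try:
            r = fisher_or(ContingencyTable2x2.from_flags(obs_kept, ev_kept))
        except ValueError:
            pass  # degenerate margin at an extreme threshold: counts only
        else:
            row.update(
                or_estimate=r.or_estimate, ci_low=r.ci_low, ci_high=r.ci_high, p=r.p
            )
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_assoc_threshold(universe: PairUniverse, grid: Sequence[float]) -> pd.DataFrame:
    """Sensitivity of the OR to the SE-trait similarity threshold.

    The indication threshold stays fixed at its default (0.9) via the
    flags already on the universe."""
    return _sweep(universe, grid, vary="assoc")


def sweep_indic_threshold(universe: PairUniverse, grid: Sequence[float]) -> pd.DataFrame:
    """Sensitivity to the SE-indication removal threshold, with the
    SE-trait threshold fixed at 0.9."""
    return _sweep(universe, grid, vary="indic")


def by_source(
    universe: PairUniverse, source: str, cfg: FilterConfig = FilterConfig()
) -> EnrichmentResult:
    """Enrichment with the evidence flag recomputed from one source only."""
    if source not in SOURCES:
        raise ValueError(f"unknown evidence source {source!r}")
    sub = PairUniverse(
        universe.df,
        list(universe.drugs.values()),
        universe.se_records,
        [a for a in universe.assocs if a.source == source],
        universe.sim,
    )
    qualified = sub.drug_traits(qualified_theta_indic=cfg.theta_indic)
    evidence = sub.best_sim_per_drug(qualified) >= cfg.theta_assoc
    t = ContingencyTable2x2.from_flags(universe.df["observed"], evidence)
    return fisher_or(t)


def _check_separation(y: np.ndarray, mu: np.ndarray) -> None:
    eps = 1e-8
    fitted_extreme = (mu < eps) | (mu > 1 - eps)
    if fitted_extreme.any() and np.all((mu[fitted_extreme] > 0.5) == (y[fitted_extreme] > 0.5)):
        raise SeparationError(
            "complete separation detected; an unpenalized logit fit is refused"
        )


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (a covariate is constant or collinear); "
            "the requested coefficient is inestimable"
        )
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    fit = model.fit(maxiter=100, tol=1e-8)
    _check_separation(np.asarray(y, dtype=float), fit.fittedvalues.to_numpy())
    return pd.DataFrame(
        {
            "term": Xc.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "z": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )


def logit_interaction(universe: PairUniverse, covariate) -> pd.DataFrame:
    """Binomial logit: observed ~ evidence * covariate.

    ``covariate`` is a column name or a per-pair numeric array aligned
    with the universe rows.  Returns the coefficient table with Wald
    standard errors and p-values.
    """
    df = universe.df
    cov = df[covariate] if isinstance(covariate, str) else pd.Series(covariate, index=df.index)
    cov = pd.to_numeric(cov, errors="raise")
    if cov.isna().any():
        raise ValueError("covariate must be defined for all pairs in the universe")
    ev = df["has_evidence"].astype(float)
    X = pd.DataFrame(
        {"evidence": ev, "covariate": cov.astype(float), "evidence:covariate": ev * cov}
    )
    return _fit_logit(X, df["observed"].astype(float).to_numpy())


def _poly_contrasts(ranks: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial contrast codes of ordinal levels
    (the coding R applies to ordered factors)."""
    levels = np.unique(ranks)
    k = len(levels)
    raw = np.vander(levels.astype(float), N=degree + 1, increasing=True)
    q, _ = np.linalg.qr(raw)
    codes = q[:, 1:]  # drop the intercept column
    lookup = {lv: codes[i] for i, lv in enumerate(levels)}
    return np.stack([lookup[r] for r in ranks])


def logit_conditional(
    observed_df: pd.DataFrame,
    covariate: str,
    treatment: str = "numeric",
    word_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Binomial logit on observed pairs: evidence ~ covariate.

    For attributes that only exist when the SE is observed (frequency,
    placebo basis), the dependent variable is the evidence flag.
    ``treatment`` is "numeric" (the value, or a word's rank, enters as a
    single linear term) or "ordinal" (orthogonal polynomial contrasts,
    giving linear and higher-order terms).  ``word_order`` supplies the
    ordered vocabulary when the covariate is a frequency word.
    """
    df = observed_df.dropna(subset=[covariate])
    if df.empty:
        raise ValueError(f"no observed pairs carry attribute {covariate!r}")
    y = df["has_evidence"].astype(float).to_numpy()
    values = df[covariate]
    if word_order is not None:
        rank_of = {w: i + 1 for i, w in enumerate(word_order)}
        unknown = set(values) - set(rank_of)
        if unknown:
            raise ValueError(f"frequency words missing from the vocabulary: {sorted(unknown)}")
        ranks = values.map(rank_of).to_numpy()
    else:
        ranks = pd.to_numeric(values, errors="raise").to_numpy()
    if treatment == "numeric":
        X = pd.DataFrame({covariate: ranks.astype(float)}, index=df.index)
    elif treatment == "ordinal":
        k = len(np.unique(ranks))
        if k < 2:
            raise ValueError("ordinal treatment needs >= 2 observed levels")
        codes = _poly_contrasts(ranks, degree=k - 1)
        names = ["linear", "quadratic", "cubic"] + [f"deg{i}" for i in range(4, k)]
        X = pd.DataFrame(
            {f"{covariate}.{names[j]}": codes[:, j] for j in range(codes.shape[1])},
            index=df.index,
        )
    else:
        raise ValueError("treatment must be 'numeric' or 'ordinal'")
    return _fit_logit(X, y)


@dataclass(frozen=True)
class StratifiedResult:
    common_or: float
    cmh_stat: float
    cmh_p: float
    heterogeneity_stat: float
    heterogeneity_p: float
    n_strata: int


def cmh_across_areas(tables: Mapping[str, ContingencyTable2x2]) -> StratifiedResult:
    """Mantel-Haenszel common OR with CMH association test and
    Breslow-Day (Tarone-adjusted) homogeneity test across strata."""
    usable = {
        k: t
        for k, t in tables.items()
        if (t.a + t.b) > 0 and (t.c + t.d) > 0 and (t.a + t.c) > 0 and (t.b + t.d) > 0
    }
    if len(usable) < 2:
        raise ValueError("stratified analysis needs >= 2 strata with non-degenerate margins")
    arr = [np.array([[t.a, t.b], [t.c, t.d]]) for t in usable.values()]
    st = StratifiedTable(arr)
    null = st.test_null_odds(correction=False)
    het = st.test_equal_odds(adjust=True)
    return StratifiedResult(
        common_or=float(st.oddsratio_pooled),
        cmh_stat=float(null.statistic),
        cmh_p=float(null.pvalue),
        heterogeneity_stat=float(het.statistic),
        heterogeneity_p=float(het.pvalue),
        n_strata=len(usable),
    )


def target_se_enrichment(
    universe: PairUniverse, fdr_q: float = 0.05, min_or: float = 2.0
) -> tuple[pd.DataFrame, list[str]]:
    """Per (target gene, SE) Fisher screen across drugs with BH control.

    The contingency unit is the drug: drugs with / without the target
    against drugs with / without the SE observed.  Targets carried by a
    single drug (or by every drug) are untestable and returned
    separately.  ``enriched`` requires OR >= ``min_or`` and BH FDR <
    ``fdr_q`` over all tested combinations.
    """
    df = universe.df
    drugs = sorted(universe.drugs)
    if len(drugs) < 2:
        raise ValueError("target enrichment needs >= 2 drugs")
    didx = {d: i for i, d in enumerate(drugs)}
    targets = sorted({g for d in universe.drugs.values() for g in d.targets})
    gidx = {g: i for i, g in enumerate(targets)}
    tmat = np.zeros((len(targets), len(drugs)), dtype=bool)
    for j, d in enumerate(drugs):
        for g in universe.drugs[d].targets:
            tmat[gidx[g], j] = True

    obs = df[df["observed"]]
    ses = sorted(obs["se_term"].unique())
    sidx = {t: i for i, t in enumerate(ses)}
    smat = np.zeros((len(drugs), len(ses)), dtype=bool)
    smat[obs["drug_id"].map(didx), obs["se_term"].map(sidx)] = True

    n_target_drugs = tmat.sum(axis=1)
    testable = (n_target_drugs >= 2) & (n_target_drugs < len(drugs))
    untestable = [g for g, ok in zip(targets, testable) if not ok]

    tm = tmat[testable]
    tnames = [g for g, ok in zip(targets, testable) if ok]
    a = (tm.astype(np.int64) @ smat.astype(np.int64))  # drugs with target & SE
    nt = tm.sum(axis=1)[:, None]
    ns = smat.sum(axis=0)[None, :]
    b = nt - a
    c = ns - a
    d = len(drugs) - nt - ns + a
    res = fisher_batch(a.ravel(), b.ravel(), c.ravel(), d.ravel())
    out = pd.DataFrame(
        {
            "target": np.repeat(tnames, len(ses)),
            "se_term": np.tile(ses, len(tnames)),
            "n_drugs_target": np.repeat(nt.ravel(), len(ses)),
            "n_drugs_target_se": a.ravel(),
            "or_estimate": res["or_cmle"],
            "p": res["p"],
        }
    )
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    with np.errstate(invalid="ignore"):
        out["enriched"] = (out["or_estimate"] >= min_or) & (out["fdr"] < fdr_q)
    return out, untestable


def pleiotropy_check(universe: PairUniverse) -> tuple[float, float]:
    """Pearson correlation of each drug's observed-SE count with the
    number of distinct traits genetically associated to its targets."""
    df = universe.df
    se_counts = df[df["observed"]].groupby("drug_id").size()
    traits = universe.drug_traits()
    drugs = sorted(universe.drugs)
    x = np.array([se_counts.get(d, 0) for d in drugs], dtype=float)
    y = np.array([len(traits[d]) for d in drugs], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in per-drug counts; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def severity_specificity_regression(se_summary: pd.DataFrame) -> tuple[float, float]:
    """OLS of log(number of drugs reporting the SE) on severity rank.

    ``se_summary`` needs columns ``n_drugs`` (>= 1) and ``severity``.
    Returns (slope, p).
    """
    df = se_summary.dropna(subset=["n_drugs", "severity"])
    df = df[df["n_drugs"] >= 1]
    if len(df) < 3:
        raise ValueError("need >= 3 side effects with severity and n_drugs >= 1")
    if df["severity"].nunique() < 2:
        raise ValueError("severity is constant; slope inestimable")
    X = sm.add_constant(df["severity"].astype(float))
    fit = sm.OLS(np.log(df["n_drugs"].astype(float)), X).fit()
    return float(fit.params["severity"]), float(fit.pvalues["severity"])
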
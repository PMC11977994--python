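"""Base rate, predictive values, and the binning schemes.

Base rate is the fraction of pairs (in a bin or overall) that are
observed.  PPV is the fraction of evidence-bearing pairs that are
observed; NPV the fraction of non-evidence pairs that are unobserved.
Bins cover drug specificity (how many drugs report the SE), severity
quartiles, disease areas (top-level ontology headings), and the
observed-only label modifiers (numeric frequency, frequency words,
placebo basis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import ContingencyTable2x2, EnrichmentResult, fisher_or
from .ontology import Ontology
from .tables import PairUniverse, SideEffectRecord


def ppv(n_evidence_observed: int, n_evidence: int) -> float:
    """Observed fraction among evidence-bearing pairs."""
    if n_evidence <= 0:
        raise ValueError("PPV undefined: no evidence-bearing pairs")
    if not 0 <= n_evidence_observed <= n_evidence:
        raise ValueError("numerator must lie in [0, denominator]")
    return n_evidence_observed / n_evidence


def npv(n_noevidence_unobserved: int, n_noevidence: int) -> float:
    """Unobserved fraction among pairs without evidence."""
    if n_noevidence <= 0:
        raise ValueError("NPV undefined: no evidence-free pairs")
    return n_noevidence_unobserved / n_noevidence


@dataclass
class BinResult:
    bin_label: str
    n_pairs: int
    n_observed: int
    n_evidence: int
    n_evidence_observed: int
    base_rate: float
    ppv: Optional[float]
    npv: Optional[float]
    enrichment: Optional[EnrichmentResult]

    def to_dict(self) -> dict:
        d = {
            "bin": self.bin_label,
            "n_pairs": self.n_pairs,
            "n_observed": self.n_observed,
            "n_evidence": self.n_evidence,
            "n_evidence_observed": self.n_evidence_observed,
            "base_rate": self.base_rate,
            "ppv": self.ppv,
            "npv": self.npv,
        }
        if self.enrichment is not None:
            d.update(
                or_estimate=self.enrichment.or_estimate,
                ci_low=self.enrichment.ci_low,
                ci_high=self.enrichment.ci_high,
                p=self.enrichment.p,
            )
        return d


def bin_results_frame(bins: Sequence[BinResult]) -> pd.DataFrame:
    return pd.DataFrame([b.to_dict() for b in bins])


def _bin_from_pairs(label: str, observed: np.ndarray, evidence: np.ndarray) -> BinResult:
    observed = np.asarray(observed, dtype=bool)
    evidence = np.asarray(evidence, dtype=bool)
    n = observed.size
    n_obs = int(observed.sum())
    n_ev = int(evidence.sum())
    n_ev_obs = int((observed & evidence).sum())
    enr = None
    if 0 < n_obs < n and 0 < n_ev < n:
        enr = fisher_or(ContingencyTable2x2.from_flags(observed, evidence))
    return BinResult(
        bin_label=label,
        n_pairs=n,
        n_observed=n_obs,
        n_evidence=n_ev,
        n_evidence_observed=n_ev_obs,
        base_rate=n_obs / n if n else float("nan"),
        ppv=n_ev_obs / n_ev if n_ev else None,
        npv=(n - n_obs - n_ev + n_ev_obs) / (n - n_ev) if n - n_ev else None,
        enrichment=enr,
    )


DEFAULT_SPECIFICITY_EDGES = (1, 2, 10, 100)


def specificity_bins(
    universe: PairUniverse, edges: Sequence[int] = DEFAULT_SPECIFICITY_EDGES
) -> list[BinResult]:
    """Bin SEs by the number of drugs for which they are observed.

    ``edges`` are left edges of consecutive integer intervals (the last
    is open-ended), defaulting to 1 / 2-9 / 10-99 / 100+.  SEs observed
    for no drug are excluded.
    """
    edges = sorted(edges)
    if len(set(edges)) != len(edges) or edges[0] < 1:
        raise ValueError("specificity edges must be distinct positive integers")
    labels = []
    for i, lo in enumerate(edges):
        hi = edges[i + 1] - 1 if i + 1 < len(edges) else None
        labels.append(f"{lo}" if hi == lo else (f"{lo}-{hi}" if hi else f"{lo}+"))
    df = universe.df
    counts = df[df["observed"]].groupby("se_term")["drug_id"].nunique()
    bin_of = pd.cut(
        counts,
        bins=list(edges) + [np.inf],
        labels=labels,
        right=False,
        include_lowest=True,
    )
    out = []
    for label in labels:
        terms = set(counts.index[bin_of == label])
        sub = df[df["se_term"].isin(terms)]
        if len(sub):
            out.append(_bin_from_pairs(label, sub["observed"], sub["has_evidence"]))
    return out


def se_severity(se_records: Sequence[SideEffectRecord]) -> pd.Series:
    """Per-SE severity rank (highest reported across records)."""
    rows = [
        (r.se_term, r.severity_rank) for r in se_records if r.severity_rank is not None
    ]
    if not rows:
        return pd.Series(dtype=float, name="severity")
    df = pd.DataFrame(rows, columns=["se_term", "severity"])
    return df.groupby("se_term")["severity"].max().rename("severity")


def severity_bins(
    universe: PairUniverse, severity: Optional[pd.Series] = None, n_bins: int = 4
) -> list[BinResult]:
    """Bin SEs by empirical quantiles of their severity rank.

    Quartile cut points come from the distribution over ranked SE terms;
    SEs without a rank form an explicit "unassigned" bin.
    """
    if severity is None:
        severity = se_severity(universe.se_records)
    df = universe.df
    ranked = severity.dropna()
    ranked = ranked[ranked.index.isin(df["se_term"].unique())]
    if ranked.nunique() < n_bins:
        raise ValueError(f"need >= {n_bins} distinct severity values to form quantile bins")
    q = pd.qcut(ranked, q=n_bins, duplicates="drop")
    labels = [f"Q{i + 1}" for i in range(len(q.cat.categories))]
    q = q.cat.rename_categories(labels)
    out = []
    for label in labels:
        terms = set(ranked.index[q == label])
        sub = df[df["se_term"].isin(terms)]
        if len(sub):
            out.append(_bin_from_pairs(label, sub["observed"], sub["has_evidence"]))
    unassigned = df[~df["se_term"].isin(set(ranked.index))]
    if len(unassigned):
        out.append(
            _bin_from_pairs("unassigned", unassigned["observed"], unassigned["has_evidence"])
        )
    return out


def area_bins(
    universe: PairUniverse, onto: Ontology, remove_same_area: bool = False
) -> list[BinResult]:
    """Per disease-area (top-level heading) results.

    An SE below several headings contributes to each.  With
    ``remove_same_area``, drugs holding any indication in the area are
    dropped from that area's pairs (the stricter confounder variant);
    this can only shrink each area's pair set.
    """
    df = universe.df
    area_of_se: dict[str, frozenset[str]] = {
        t: onto.top_level_headings(t) for t in df["se_term"].unique()
    }
    areas = sorted({a for s in area_of_se.values() for a in s})
    out = []
    for area in areas + ["unclassified"]:
        if area == "unclassified":
            terms = {t for t, s in area_of_se.items() if not s}
        else:
            terms = {t for t, s in area_of_se.items() if area in s}
        if not terms:
            continue
        sub = df[df["se_term"].isin(terms)]
        if remove_same_area and area != "unclassified":
            bad_drugs = {
                d.drug_id
                for d in universe.drugs.values()
                if any(
                    area in onto.top_level_headings(i) for i in d.indications if i in onto
                )
            }
            sub = sub[~sub["drug_id"].isin(bad_drugs)]
        if len(sub):
            out.append(_bin_from_pairs(area, sub["observed"], sub["has_evidence"]))
    return out


DEFAULT_FREQ_EDGES = (0.01, 0.10)


def attach_modifiers(universe: PairUniverse) -> pd.DataFrame:
    """Universe rows joined with the modifier fields of observed records."""
    recs = pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "se_term": r.se_term,
                "freq_numeric": r.freq_numeric,
                "freq_word": r.freq_word,
                "placebo": r.placebo,
                "severity_rank": r.severity_rank,
            }
            for r in universe.se_records
        ]
    )
    if recs.empty:
        recs = pd.DataFrame(
            columns=["drug_id", "se_term", "freq_numeric", "freq_word", "placebo", "severity_rank"]
        )
    recs = recs.drop_duplicates(subset=["drug_id", "se_term"])
    return universe.df.merge(recs, on=["drug_id", "se_term"], how="left")


def modifier_bins(
    universe: PairUniverse,
    modifier: str,
    numeric_edges: Sequence[float] = DEFAULT_FREQ_EDGES,
    word_order: Optional[Sequence[str]] = None,
) -> list[BinResult]:
    """Conditional enrichment by label modifier.

    The modifiers only exist when the SE is observed, so each bin's 2x2
    contrasts pairs *observed with the attribute* against all other
    pairs in the universe, crossed with evidence ("enrichment of genetic
    evidence conditioned on an SE being observed with the indicated
    modifier").  ``modifier`` is one of freq_numeric / freq_word /
    placebo.
    """
    df = attach_modifiers(universe)
    ev = df["has_evidence"].to_numpy(dtype=bool)
    if modifier == "freq_numeric":
        edges = [0.0] + sorted(numeric_edges) + [1.0]
        labels = [f"<={edges[1]:g}"] + [
            f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(1, len(edges) - 2)
        ] + [f">{edges[-2]:g}"]
        values = pd.cut(df["freq_numeric"], bins=edges, labels=labels, include_lowest=True)
    elif modifier == "freq_word":
        values = df["freq_word"]
        labels = list(word_order) if word_order else sorted(values.dropna().unique())
    elif modifier == "placebo":
        values = df["placebo"]
        labels = [False, True]
    else:
        raise ValueError(f"unknown modifier {modifier!r}")
    out = []
    for label in labels:
        with_attr = (values == label) & df["observed"]
        if not with_attr.any():
            continue
        out.append(_bin_from_pairs(str(label), with_attr.to_numpy(), ev))
    return out
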
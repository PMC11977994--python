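"""Confounder controls for the drug x side-effect enrichment analysis.

Two filters are applied before any enrichment statistic:

* **genetic insight** — a side effect only enters the analysis if it (or
  a trait with similarity >= 0.8 to it) has actually been studied
  genetically: at least one Mendelian/somatic-driver gene (OMIM or
  IntOGen) or at least three GWAS hits at distinct loci, loci being
  (chromosome, position rounded to the nearest megabase) bins;
* **similar indication** — pairs where any approved indication of the
  drug has similarity >= 0.9 to the SE are removed, so SEs that merely
  co-occur with the treated disease do not masquerade as on-target
  liabilities.

The evidence flag itself applies the indication rule per association:
an association whose trait is similar (>= theta_indic) to one of the
drug's indications is disqualified *before* the per-drug maximum over
trait-SE similarities is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import SimilarityMatrix
from .tables import DrugRecord, GeneticAssociation, PairUniverse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InsightConfig:
    """Thresholds defining which traits count as genetically studied."""

    sim_threshold: float = 0.8
    min_mendelian_genes: int = 1
    min_gwas_loci: int = 3
    gwas_sources: frozenset[str] = frozenset({"OTG", "PICCOLO"})
    mendelian_sources: frozenset[str] = frozenset({"OMIM", "IntOGen"})

    def __post_init__(self):
        if not (0.0 <= self.sim_threshold <= 1.0):
            raise ValueError("sim_threshold must be in [0, 1]")
        if self.min_mendelian_genes < 1 or self.min_gwas_loci < 1:
            raise ValueError("minimum counts must be >= 1")


@dataclass(frozen=True)
class FilterConfig:
    """Similarity thresholds for evidence and the indication filter."""

    theta_assoc: float = 0.9
    theta_indic: float = 0.9
    require_insight: bool = True

    def __post_init__(self):
        if not (0.0 <= self.theta_assoc <= 1.0) or not (0.0 <= self.theta_indic <= 1.01):
            raise ValueError("thresholds must be in [0, 1]")


def insight_terms(
    assocs: Sequence[GeneticAssociation],
    sim: SimilarityMatrix,
    cfg: InsightConfig = InsightConfig(),
) -> frozenset[str]:
    """Terms with genetic insight.

    A trait *qualifies* if it has >= ``min_mendelian_genes`` distinct
    genes from the Mendelian/somatic sources, or >= ``min_gwas_loci``
    GWAS hits at distinct (chromosome, megabase) bins.  A term has
    insight if it qualifies itself or any trait with similarity >=
    ``sim_threshold`` to it qualifies.
    """
    mend_genes: dict[str, set[str]] = {}
    gwas_loci: dict[str, set[tuple[str, int]]] = {}
    for a in assocs:
        if a.source in cfg.mendelian_sources:
            mend_genes.setdefault(a.trait_term, set()).add(a.gene)
        elif a.source in cfg.gwas_sources:
            if a.locus is None:
                raise ValueError(
                    f"GWAS-source association {a.gene}-{a.trait_term} ({a.source}) "
                    "lacks a locus; chromosome and megabase are required for "
                    "insight counting"
                )
            gwas_loci.setdefault(a.trait_term, set()).add(a.locus)
    qualifying = {t for t, g in mend_genes.items() if len(g) >= cfg.min_mendelian_genes}
    qualifying |= {t for t, l in gwas_loci.items() if len(l) >= cfg.min_gwas_loci}
    qualifying &= set(sim.terms)
    if not qualifying:
        return frozenset()
    qlist = sorted(qualifying)
    block = sim.submatrix(sim.terms, qlist)
    reach = block.max(axis=1) >= cfg.sim_threshold
    out = {t for t, r in zip(sim.terms, reach) if r}
    return frozenset(out | qualifying)


def flag_evidence(
    universe: PairUniverse,
    cfg: FilterConfig = FilterConfig(),
    insight_cfg: InsightConfig = InsightConfig(),
) -> PairUniverse:
    """Populate has_evidence / excluded_similar_indication / insight flags.

    ``has_evidence`` is true when the best *qualified* association
    similarity meets ``theta_assoc``; associations whose trait is similar
    (>= ``theta_indic``) to one of the drug's approved indications are
    disqualified before the maximum.  The qualified best similarity is
    kept in column ``best_assoc_sim_qualified`` so threshold sweeps can
    re-threshold without recomputation.
    """
    df = universe.df
    qualified = universe.drug_traits(qualified_theta_indic=cfg.theta_indic)
    df["best_assoc_sim_qualified"] = universe.best_sim_per_drug(qualified)
    df["has_evidence"] = df["best_assoc_sim_qualified"] >= cfg.theta_assoc
    df["excluded_similar_indication"] = df["best_indic_sim"] >= cfg.theta_indic
    terms_with_insight = insight_terms(universe.assocs, universe.sim, insight_cfg)
    df["insight"] = df["se_term"].isin(terms_with_insight)
    return universe


@dataclass
class FilterReport:
    n_pairs: int
    n_observed: int
    n_removed_insight: int
    n_removed_similar_indication: int
    n_removed_joint: int
    n_retained: int
    observed_removed_similar_indication: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def apply_filters(
    universe: PairUniverse,
    cfg: FilterConfig = FilterConfig(),
    insight_cfg: InsightConfig = InsightConfig(),
) -> tuple[PairUniverse, FilterReport]:
    """Retain pairs whose SE has insight and is not indication-similar.

    Returns the retained sub-universe plus a removal report (counts per
    filter separately and jointly; the similar-indication removal is also
    reported among observed pairs, the scale on which it is usually
    quoted).
    """
    if "has_evidence" not in universe.df.columns:
        universe = flag_evidence(universe, cfg, insight_cfg)
    df = universe.df
    no_insight = ~df["insight"] if cfg.require_insight else pd.Series(False, index=df.index)
    similar = df["excluded_similar_indication"]
    keep = ~(no_insight | similar)
    report = FilterReport(
        n_pairs=len(df),
        n_observed=int(df["observed"].sum()),
        n_removed_insight=int(no_insight.sum()),
        n_removed_similar_indication=int(similar.sum()),
        n_removed_joint=int((no_insight & similar).sum()),
        n_retained=int(keep.sum()),
        observed_removed_similar_indication=int((similar & df["observed"]).sum()),
    )
    if report.n_retained == 0:
        raise ValueError(
            "all pairs removed by the confounder filters; review theta_indic "
            "and the insight thresholds"
        )
    logger.info(
        "filters removed %d pairs (insight %d, similar indication %d, joint %d)",
        report.n_pairs - report.n_retained,
        report.n_removed_insight,
        report.n_removed_similar_indication,
        report.n_removed_joint,
    )
    return universe.subset(keep), report


def flag_indication_support(
    drugs: Sequence[DrugRecord],
    support_table: pd.DataFrame,
    sim: SimilarityMatrix,
    threshold: float = 0.8,
) -> dict[str, bool]:
    """Per-drug flag: any approved indication genetically supported?

    ``support_table`` has columns ``drug_id`` and ``trait_term`` listing
    the genetically supported traits of each drug's target.  A drug is
    supported when any (indication, supported trait) similarity meets the
    threshold.
    """
    traits_by_drug: dict[str, set[str]] = {}
    for row in support_table.itertuples(index=False):
        traits_by_drug.setdefault(str(row.drug_id), set()).add(str(row.trait_term))
    out: dict[str, bool] = {}
    for d in drugs:
        traits = sorted(traits_by_drug.get(d.drug_id, ()))
        if not traits:
            out[d.drug_id] = False
            continue
        s = sim.submatrix(sorted(d.indications), traits)
        out[d.drug_id] = bool(s.max() >= threshold)
    return out


def attach_indication_support(universe: PairUniverse, supported: Mapping[str, bool]) -> None:
    universe.df["indication_genetic_support"] = (
        universe.df["drug_id"].map(dict(supported)).fillna(False).astype(bool)
    )


def megabase_bin(pos_bp: int) -> int:
    """Locus bin: position rounded to the nearest megabase."""
    return int(round(pos_bp / 1e6))
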
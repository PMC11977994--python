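"""Analytic tables and the drug x side-effect pair universe.

Three input tables drive the analysis:

* drugs, each with >=1 human gene target and >=1 approved indication
  (ontology terms);
* drug-side-effect records, with optional label modifiers (numeric
  frequency, frequency word, placebo basis, severity rank);
* gene-trait genetic associations from a closed set of evidence sources,
  with an optional locus for GWAS-type sources.

The unit of analysis is the *pair universe*: the full cross product of
retained drugs with the distinct side-effect terms appearing anywhere in
the side-effect table.  A pair is *observed* when the SE appears on that
drug's label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ontology import SimilarityMatrix

logger = logging.getLogger(__name__)

SOURCES = frozenset({"OMIM", "OTG", "PICCOLO", "Genebass", "IntOGen"})


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    targets: frozenset[str]
    indications: frozenset[str]

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"drug {self.drug_id} has no targets")
        if not self.indications:
            raise ValueError(f"drug {self.drug_id} has no indications")


@dataclass(frozen=True)
class SideEffectRecord:
    drug_id: str
    se_term: str
    freq_numeric: Optional[float] = None
    freq_word: Optional[str] = None
    placebo: Optional[bool] = None
    severity_rank: Optional[int] = None

    def __post_init__(self):
        if self.freq_numeric is not None and not (0.0 <= self.freq_numeric <= 1.0):
            raise ValueError(
                f"freq_numeric {self.freq_numeric} outside [0, 1] "
                f"for ({self.drug_id}, {self.se_term})"
            )
        if self.severity_rank is not None and self.severity_rank < 1:
            raise ValueError("severity_rank must be >= 1")


@dataclass(frozen=True)
class GeneticAssociation:
    gene: str
    trait_term: str
    source: str
    chrom: Optional[str] = None
    pos_mb: Optional[int] = None

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(
                f"unknown evidence source {self.source!r}; expected one of {sorted(SOURCES)}"
            )

    @property
    def locus(self) -> Optional[tuple[str, int]]:
        if self.chrom is None or self.pos_mb is None:
            return None
        return (self.chrom, self.pos_mb)


def _opt_float(v):
    return None if pd.isna(v) or v == "" else float(v)


def _opt_str(v):
    return None if pd.isna(v) or v == "" else str(v)


def _opt_bool(v):
    if pd.isna(v) or v == "":
        return None
    s = str(v).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no"}:
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def _opt_int(v):
    return None if pd.isna(v) or v == "" else int(float(v))


def load_tables(drug_tsv, se_tsv, assoc_tsv):
    """Load and validate the three analytic tables.

    Drugs violating the >=1 target / >=1 indication invariant are dropped
    with a logged count; malformed rows raise with their line number.

    Returns ``(drugs, se_records, associations)``.
    """
    drugs: list[DrugRecord] = []
    dropped = 0
    ddf = pd.read_csv(drug_tsv, sep="\t", dtype=str)
    _require_columns(ddf, ["drug_id", "targets", "indications"], drug_tsv)
    for pos, row in enumerate(ddf.itertuples(index=False), start=2):
        targets = _split(row.targets)
        indications = _split(row.indications)
        if not targets or not indications:
            dropped += 1
            continue
        if pd.isna(row.drug_id) or not str(row.drug_id):
            raise ValueError(f"{drug_tsv} line {pos}: missing drug_id")
        drugs.append(
            DrugRecord(str(row.drug_id), frozenset(targets), frozenset(indications))
        )
    if dropped:
        logger.warning(
            "dropped %d drugs lacking a target or an approved indication", dropped
        )
    if len({d.drug_id for d in drugs}) != len(drugs):
        raise ValueError(f"{drug_tsv}: duplicate drug_id rows")

    ses: list[SideEffectRecord] = []
    sdf = pd.read_csv(se_tsv, sep="\t", dtype=str)
    _require_columns(
        sdf,
        ["drug_id", "se_term", "freq_numeric", "freq_word", "placebo", "severity_rank"],
        se_tsv,
    )
    if sdf.empty:
        logger.warning("side-effect table %s is empty", se_tsv)
    for pos, row in enumerate(sdf.itertuples(index=False), start=2):
        try:
            ses.append(
                SideEffectRecord(
                    drug_id=str(row.drug_id),
                    se_term=str(row.se_term),
                    freq_numeric=_opt_float(row.freq_numeric),
                    freq_word=_opt_str(row.freq_word),
                    placebo=_opt_bool(row.placebo),
                    severity_rank=_opt_int(row.severity_rank),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{se_tsv} line {pos}: {exc}") from exc

    assocs: list[GeneticAssociation] = []
    adf = pd.read_csv(assoc_tsv, sep="\t", dtype=str)
    _require_columns(adf, ["gene", "trait_term", "source", "chrom", "pos_mb"], assoc_tsv)
    for pos, row in enumerate(adf.itertuples(index=False), start=2):
        try:
            assocs.append(
                GeneticAssociation(
                    gene=str(row.gene),
                    trait_term=str(row.trait_term),
                    source=str(row.source),
                    chrom=_opt_str(row.chrom),
                    pos_mb=_opt_int(row.pos_mb),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{assoc_tsv} line {pos}: {exc}") from exc
    return drugs, ses, assocs


def _split(v) -> list[str]:
    if pd.isna(v) or not str(v).strip():
        return []
    return [tok for tok in str(v).split(";") if tok]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    if list(df.columns) != list(cols):
        raise ValueError(f"{path}: expected columns {list(cols)}, got {list(df.columns)}")


class PairUniverse:
    """Cross product of drugs x SE terms with per-pair analysis flags.

    ``df`` carries one row per pair with columns: drug_id, se_term,
    observed, best_assoc_sim, best_indic_sim, and (after flagging)
    has_evidence, insight, excluded_similar_indication,
    indication_genetic_support.  References to the source records and the
    similarity matrix are kept so filters and sweeps can recompute flags.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        drugs: Sequence[DrugRecord],
        se_records: Sequence[SideEffectRecord],
        assocs: Sequence[GeneticAssociation],
        sim: SimilarityMatrix,
    ):
        self.df = df
        self.drugs = {d.drug_id: d for d in drugs}
        self.se_records = list(se_records)
        self.assocs = list(assocs)
        self.sim = sim

    @property
    def se_terms(self) -> list[str]:
        return sorted(self.df["se_term"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "PairUniverse":
        return PairUniverse(
            self.df[mask].reset_index(drop=True),
            list(self.drugs.values()),
            self.se_records,
            self.assocs,
            self.sim,
        )

    def drug_traits(self, qualified_theta_indic: float | None = None) -> dict[str, list[str]]:
        """Trait terms genetically associated to each drug's targets.

        With ``qualified_theta_indic`` set, traits whose similarity to any
        of the drug's approved indications meets that threshold are
        disqualified (the confounder rule applied per association, before
        any maximum is taken).
        """
        by_gene: dict[str, set[str]] = {}
        for a in self.assocs:
            by_gene.setdefault(a.gene, set()).add(a.trait_term)
        out: dict[str, list[str]] = {}
        for drug in self.drugs.values():
            traits = set()
            for g in drug.targets:
                traits |= by_gene.get(g, set())
            if qualified_theta_indic is not None and traits:
                indics = sorted(drug.indications)
                tlist = sorted(traits)
                s = self.sim.submatrix(tlist, indics)
                keep = s.max(axis=1) < qualified_theta_indic
                traits = {t for t, k in zip(tlist, keep) if k}
            out[drug.drug_id] = sorted(traits)
        return out

    def best_sim_per_drug(self, traits_by_drug: Mapping[str, Sequence[str]]) -> np.ndarray:
        """Max similarity of each SE term to each drug's trait set.

        Returns an array aligned with ``self.df`` rows.
        """
        ses = self.se_terms
        se_idx = {t: i for i, t in enumerate(ses)}
        per_drug = {}
        for drug_id, traits in traits_by_drug.items():
            if traits:
                per_drug[drug_id] = self.sim.submatrix(traits, ses).max(axis=0)
            else:
                per_drug[drug_id] = np.zeros(len(ses))
        drug_list = sorted(per_drug)
        mat = np.stack([per_drug[d] for d in drug_list])
        di = self.df["drug_id"].map({d: i for i, d in enumerate(drug_list)}).to_numpy()
        cols = self.df["se_term"].map(se_idx).to_numpy()
        return mat[di, cols]


def build_universe(
    drugs: Sequence[DrugRecord],
    ses: Sequence[SideEffectRecord],
    sim: SimilarityMatrix,
    assocs: Sequence[GeneticAssociation],
) -> PairUniverse:
    """Construct the full drug x SE-term pair universe.

    One row per (drug, SE term) in the cross product; ``observed`` marks
    pairs with a side-effect record; ``best_assoc_sim`` is the maximum
    similarity between the SE and any trait genetically associated to any
    of the drug's targets (0 when there is none); ``best_indic_sim`` the
    maximum similarity between the SE and any approved indication.
    """
    if not drugs:
        raise ValueError("no drugs; cannot build a pair universe")
    se_terms = sorted({r.se_term for r in ses})
    missing = [t for t in se_terms if t not in sim]
    missing += sorted({t for d in drugs for t in d.indications if t not in sim})
    missing += sorted({a.trait_term for a in assocs if a.trait_term not in sim})
    if missing:
        raise ValueError(f"terms missing from similarity matrix: {sorted(set(missing))}")

    drug_ids = sorted(d.drug_id for d in drugs)
    idx = pd.MultiIndex.from_product([drug_ids, se_terms], names=["drug_id", "se_term"])
    df = idx.to_frame(index=False)
    observed_keys = {(r.drug_id, r.se_term) for r in ses}
    df["observed"] = [
        (d, t) in observed_keys for d, t in zip(df["drug_id"], df["se_term"])
    ]

    uni = PairUniverse(df, drugs, ses, assocs, sim)
    traits = uni.drug_traits(qualified_theta_indic=None)
    df["best_assoc_sim"] = uni.best_sim_per_drug(traits)
    indics = {d.drug_id: sorted(d.indications) for d in drugs}
    df["best_indic_sim"] = uni.best_sim_per_drug(indics)
    return uni


def overall_base_rate(universe: PairUniverse) -> float:
    """Marginal probability of a pair being observed (observed / total)."""
    n = len(universe.df)
    if n == 0:
        raise ValueError("empty pair universe")
    return float(universe.df["observed"].sum()) / n
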
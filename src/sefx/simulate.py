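"""Seeded synthetic data with the joint structure the analysis assumes.

The generator emits a complete input set — ontology, annotation corpus,
drugs with targets and indications, drug-SE records with modifiers,
gene-trait associations with sources and loci — plus a truth record of
every planted parameter, so the whole pipeline is testable without any
external download.

Observation model: each (drug, SE-term) pair is observed with

    logit P(observed) = alpha + beta_evidence * E + gamma_indic * I

where ``E`` flags pairs whose drug has a qualified genetic association
(similarity >= 0.9 between the trait and the SE, associations similar to
an approved indication disqualified — the same rule the pipeline's
evidence flag applies) and ``I`` flags pairs where an approved
indication is similar (>= 0.9) to the SE.  ``gamma_indic`` therefore
plants exactly the confounding-by-indication the similar-indication
filter exists to remove.  ``alpha`` is solved so the marginal base rate
matches its target (default 5.4%).

Similarities are the package's own combined Lin-Resnik scores computed
on the generated ontology and corpus, so "similar" means the same thing
to the generator and to the pipeline under test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .enrichment import ContingencyTable2x2, EnrichmentResult, fisher_or
from .filters import FilterConfig, InsightConfig, apply_filters, flag_evidence
from .ontology import AnnotationCorpus, Ontology, SimilarityMatrix, pairwise_similarity
from .tables import DrugRecord, GeneticAssociation, PairUniverse, SideEffectRecord, build_universe

DEFAULT_FREQ_WORDS = ("very rare", "rare", "uncommon", "common", "very common")
_FREQ_WORD_EDGES = (0.005, 0.02, 0.08, 0.2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    The default scale (300 terms, 200 genes, 150 drugs, ~tens of
    thousands of pairs) runs in seconds on a desktop; the planted
    conditional log-OR ``beta_evidence`` defaults to log 2 (the headline
    effect size) and the marginal base rate target to 5.4%.
    """

    seed: int = 0
    n_terms: int = 300
    n_top_level: int = 12
    dag_depth: int = 5
    n_genes: int = 200
    n_drugs: int = 150
    targets_per_drug: tuple[int, int] = (1, 3)
    indications_per_drug: tuple[int, int] = (1, 3)
    assocs_per_gene_mean: float = 3.0
    source_mix: tuple[tuple[str, float], ...] = (
        ("OMIM", 0.25),
        ("OTG", 0.35),
        ("PICCOLO", 0.15),
        ("Genebass", 0.15),
        ("IntOGen", 0.10),
    )
    beta_evidence: float = math.log(2.0)
    gamma_indic: float = math.log(3.0)
    alpha: Optional[float] = None
    base_rate_target: float = 0.054
    theta_assoc: float = 0.9
    theta_indic: float = 0.9
    severity_coupling: float = -0.5
    severity_assigned_frac: float = 0.75
    freq_numeric_frac: float = 0.45
    freq_word_frac: float = 0.5
    placebo_frac: float = 0.6
    freq_evidence_shift: float = 0.6
    placebo_evidence_shift: float = 0.0
    freq_words: tuple[str, ...] = DEFAULT_FREQ_WORDS
    indication_support_rate: float = 0.15

    def __post_init__(self):
        if self.n_drugs < 2 or self.n_terms < 2:
            raise ValueError("need at least 2 drugs and 2 terms")
        if self.n_top_level + 1 >= self.n_terms:
            raise ValueError("n_terms must exceed n_top_level + 1 (the root)")
        mix = dict(self.source_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
            raise ValueError("source_mix must be a probability distribution")
        for frac in (
            self.severity_assigned_frac,
            self.freq_numeric_frac,
            self.freq_word_frac,
            self.placebo_frac,
            self.indication_support_rate,
            self.base_rate_target,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    cfg: GeneratorConfig
    onto: Ontology
    corpus: AnnotationCorpus
    sim: SimilarityMatrix
    drugs: list[DrugRecord]
    se_records: list[SideEffectRecord]
    assocs: list[GeneticAssociation]
    support_table: pd.DataFrame
    se_vocab: list[str]
    truth: dict

    @property
    def latent(self) -> pd.DataFrame:
        """Per-pair latent flags and observation probability."""
        return self.truth["latent"]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.onto.to_tsv(out / "ontology.tsv")
        self.corpus.to_tsv(out / "corpus.tsv")
        (out / "top_level.txt").write_text(
            "".join(t + "\n" for t in sorted(self.onto.top_level))
        )
        self.sim.to_tsv(out / "similarity.tsv")
        pd.DataFrame(
            {
                "drug_id": [d.drug_id for d in self.drugs],
                "targets": [";".join(sorted(d.targets)) for d in self.drugs],
                "indications": [";".join(sorted(d.indications)) for d in self.drugs],
            }
        ).to_csv(out / "drugs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "drug_id": r.drug_id,
                    "se_term": r.se_term,
                    "freq_numeric": r.freq_numeric,
                    "freq_word": r.freq_word,
                    "placebo": r.placebo,
                    "severity_rank": r.severity_rank,
                }
                for r in self.se_records
            ]
        ).to_csv(out / "side_effects.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene": a.gene,
                    "trait_term": a.trait_term,
                    "source": a.source,
                    "chrom": a.chrom,
                    "pos_mb": a.pos_mb,
                }
                for a in self.assocs
            ]
        ).to_csv(out / "associations.tsv", sep="\t", index=False)
        self.support_table.to_csv(out / "indication_support.tsv", sep="\t", index=False)
        params = {k: v for k, v in self.truth.items() if k != "latent"}
        params["config"] = asdict(self.cfg)
        (out / "truth.json").write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
        self.latent.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)


def _build_dag(cfg: GeneratorConfig, rng: np.random.Generator):
    """Layered random DAG: a root, the top-level layer, then geometric
    layers where each term attaches to 1-2 parents in the layer above."""
    terms = [f"T{i:04d}" for i in range(cfg.n_terms)]
    root = terms[0]
    top = terms[1 : 1 + cfg.n_top_level]
    edges = [(t, root) for t in top]
    remaining = terms[1 + cfg.n_top_level :]
    n_layers = max(1, cfg.dag_depth - 1)
    weights = np.array([1.5**i for i in range(n_layers)])
    sizes = np.maximum(1, np.round(weights / weights.sum() * len(remaining)).astype(int))
    while sizes.sum() > len(remaining):
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < len(remaining):
        sizes[np.argmax(weights)] += 1
    prev = top
    pos = 0
    for size in sizes:
        layer = remaining[pos : pos + size]
        pos += size
        for t in layer:
            k = int(rng.integers(1, 3))
            parents = rng.choice(len(prev), size=min(k, len(prev)), replace=False)
            for p in parents:
                edges.append((t, prev[p]))
        prev = layer
    return Ontology(edges, top_level=top), root, top


def _solve_alpha(e_flag, i_flag, beta, gamma, target) -> float:
    lo, hi = -20.0, 5.0
    shift = beta * e_flag + gamma * i_flag
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + shift).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(cfg: GeneratorConfig = GeneratorConfig(), out_dir=None) -> SyntheticDataset:
    """Generate a complete synthetic dataset (optionally written as TSVs).

    The same seed yields byte-identical files."""
    rng = np.random.default_rng(cfg.seed)
    onto, root, top = _build_dag(cfg, rng)
    counts = np.round(rng.lognormal(mean=1.0, sigma=1.4, size=cfg.n_terms)).astype(int)
    corpus = AnnotationCorpus(dict(zip(onto.terms, (int(c) for c in counts))))
    sim = pairwise_similarity(onto, corpus, smooth=True)

    non_root = [t for t in onto.terms if t != root]
    se_vocab = sorted(set(non_root) - set(top))

    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    sources, probs = zip(*cfg.source_mix)
    gwas_like = {"OTG", "PICCOLO"}
    assocs: list[GeneticAssociation] = []
    for g in genes:
        n = 1 + int(rng.poisson(max(0.0, cfg.assocs_per_gene_mean - 1.0)))
        for _ in range(n):
            trait = non_root[int(rng.integers(len(non_root)))]
            src = sources[int(rng.choice(len(sources), p=probs))]
            if src in gwas_like:
                chrom = str(int(rng.integers(1, 23)))
                pos_mb = int(rng.integers(0, 250))
            else:
                chrom = pos_mb = None
            assocs.append(GeneticAssociation(g, trait, src, chrom, pos_mb))

    drugs: list[DrugRecord] = []
    for i in range(cfg.n_drugs):
        nt = int(rng.integers(cfg.targets_per_drug[0], cfg.targets_per_drug[1] + 1))
        ni = int(rng.integers(cfg.indications_per_drug[0], cfg.indications_per_drug[1] + 1))
        targets = rng.choice(len(genes), size=nt, replace=False)
        indics = rng.choice(len(non_root), size=ni, replace=False)
        drugs.append(
            DrugRecord(
                f"D{i:03d}",
                frozenset(genes[j] for j in targets),
                frozenset(non_root[j] for j in indics),
            )
        )

    # latent per-pair flags, using the pipeline's own similarity metric
    by_gene: dict[str, set[str]] = {}
    for a in assocs:
        by_gene.setdefault(a.gene, set()).add(a.trait_term)
    n_pairs = len(drugs) * len(se_vocab)
    e_flag = np.zeros((len(drugs), len(se_vocab)), dtype=bool)
    i_flag = np.zeros_like(e_flag)
    for di, d in enumerate(drugs):
        traits = sorted(set().union(*(by_gene.get(g, set()) for g in d.targets)) or set())
        indics = sorted(d.indications)
        if traits:
            s_ti = sim.submatrix(traits, indics)
            qualified = [t for t, row in zip(traits, s_ti) if row.max() < cfg.theta_indic]
            if qualified:
                e_flag[di] = sim.submatrix(qualified, se_vocab).max(axis=0) >= cfg.theta_assoc
        i_flag[di] = sim.submatrix(indics, se_vocab).max(axis=0) >= cfg.theta_indic

    alpha = cfg.alpha
    if alpha is None:
        alpha = _solve_alpha(e_flag, i_flag, cfg.beta_evidence, cfg.gamma_indic, cfg.base_rate_target)
    p_obs = expit(alpha + cfg.beta_evidence * e_flag + cfg.gamma_indic * i_flag)
    observed = rng.random(p_obs.shape) < p_obs

    # per-SE severity, coupled to drug specificity
    n_drugs_per_se = observed.sum(axis=0)
    latent_sev = cfg.severity_coupling * np.log1p(n_drugs_per_se) + rng.normal(
        0.0, 1.0, size=len(se_vocab)
    )
    assigned = rng.random(len(se_vocab)) < cfg.severity_assigned_frac
    sev_rank = np.full(len(se_vocab), -1)
    order = np.argsort(latent_sev[assigned], kind="stable")
    ranks = np.empty(order.size, dtype=int)
    ranks[order] = np.arange(1, order.size + 1)
    sev_rank[assigned] = ranks

    word_edges = np.array(_FREQ_WORD_EDGES)
    se_records: list[SideEffectRecord] = []
    for di, d in enumerate(drugs):
        for si in np.flatnonzero(observed[di]):
            f = float(rng.beta(0.8, 6.0))
            if e_flag[di, si]:
                f = f ** (1.0 / (1.0 + cfg.freq_evidence_shift))
            freq_numeric = round(f, 4) if rng.random() < cfg.freq_numeric_frac else None
            freq_word = (
                cfg.freq_words[
                    min(int(np.searchsorted(word_edges, f)), len(cfg.freq_words) - 1)
                ]
                if rng.random() < cfg.freq_word_frac
                else None
            )
            placebo = None
            if rng.random() < cfg.placebo_frac:
                placebo = bool(
                    rng.random()
                    < expit(cfg.placebo_evidence_shift * float(e_flag[di, si]))
                )
            severity = int(sev_rank[si]) if sev_rank[si] > 0 else None
            se_records.append(
                SideEffectRecord(
                    drug_id=d.drug_id,
                    se_term=se_vocab[si],
                    freq_numeric=freq_numeric,
                    freq_word=freq_word,
                    placebo=placebo,
                    severity_rank=severity,
                )
            )

    support_rows = []
    for d in drugs:
        if rng.random() < cfg.indication_support_rate:
            indics = sorted(d.indications)
            support_rows.append(
                {"drug_id": d.drug_id, "trait_term": indics[int(rng.integers(len(indics)))]}
            )
    support_table = pd.DataFrame(support_rows, columns=["drug_id", "trait_term"])

    latent = pd.DataFrame(
        {
            "drug_id": np.repeat([d.drug_id for d in drugs], len(se_vocab)),
            "se_term": np.tile(se_vocab, len(drugs)),
            "evidence": e_flag.ravel(),
            "indication_similar": i_flag.ravel(),
            "p_observed": np.round(p_obs.ravel(), 8),
            "observed": observed.ravel(),
        }
    )
    truth = {
        "alpha": alpha,
        "beta_evidence": cfg.beta_evidence,
        "gamma_indic": cfg.gamma_indic,
        "base_rate_target": cfg.base_rate_target,
        "n_pairs": int(n_pairs),
        "n_observed": int(observed.sum()),
        "evidence_prevalence": float(e_flag.mean()),
        "indication_similar_prevalence": float(i_flag.mean()),
        "latent": latent,
    }
    ds = SyntheticDataset(
        cfg=cfg,
        onto=onto,
        corpus=corpus,
        sim=sim,
        drugs=drugs,
        se_records=se_records,
        assocs=assocs,
        support_table=support_table,
        se_vocab=se_vocab,
        truth=truth,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def build_pipeline_universe(
    ds: SyntheticDataset,
    filter_cfg: FilterConfig = FilterConfig(),
    insight_cfg: InsightConfig = InsightConfig(),
):
    """Run the analysis pipeline on a dataset: universe, flags, filters.

    Returns ``(retained_universe, filter_report)``."""
    uni = build_universe(ds.drugs, ds.se_records, ds.sim, ds.assocs)
    flag_evidence(uni, filter_cfg, insight_cfg)
    return apply_filters(uni, filter_cfg, insight_cfg)


def truth_eval(ds: SyntheticDataset, universe: PairUniverse) -> dict:
    """Confusion of pipeline evidence flags against the planted latent
    flags, on the universe rows (keys must match the dataset)."""
    if universe.sim.terms != ds.sim.terms or not np.array_equal(
        universe.sim.values, ds.sim.values
    ):
        raise ValueError(
            "universe was not built from this dataset (similarity mismatch); "
            "mismatched run IDs"
        )
    merged = universe.df.merge(
        ds.latent[["drug_id", "se_term", "evidence"]],
        on=["drug_id", "se_term"],
        how="left",
        validate="one_to_one",
    )
    if merged["evidence"].isna().any():
        raise ValueError("universe rows missing from the truth record; mismatched run?")
    pred = merged["has_evidence"].to_numpy(dtype=bool)
    true = merged["evidence"].to_numpy(dtype=bool)
    return {
        "tp": int((pred & true).sum()),
        "fp": int((pred & ~true).sum()),
        "fn": int((~pred & true).sum()),
        "tn": int((~pred & ~true).sum()),
    }


def replicate_enrichment(
    ds: SyntheticDataset,
    n_replicates: int,
    seed: int,
    filter_cfg: FilterConfig = FilterConfig(),
    insight_cfg: InsightConfig = InsightConfig(),
) -> list[EnrichmentResult]:
    """Primary enrichment over fresh observation draws of one design.

    The design (similarities, flags, filters) is fixed by the dataset;
    each replicate redraws the per-pair observation Bernoullis from the
    planted probabilities and recomputes the Fisher enrichment on the
    retained universe.
    """
    latent = ds.latent.set_index(["drug_id", "se_term"])
    uni, _ = build_pipeline_universe(ds, filter_cfg, insight_cfg)
    keys = pd.MultiIndex.from_frame(uni.df[["drug_id", "se_term"]])
    p = latent.loc[keys, "p_observed"].to_numpy()
    evidence = uni.df["has_evidence"].to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        obs = rng.random(p.size) < p
        out.append(fisher_or(ContingencyTable2x2.from_flags(obs, evidence)))
    return out


def recovery_report(results: Sequence[EnrichmentResult], beta_true: float) -> dict:
    """Bias, RMSE and CI coverage of the log-OR across replicates."""
    logs = np.array([math.log(r.or_estimate) for r in results])
    cover = np.array([r.ci_low <= math.exp(beta_true) <= r.ci_high for r in results])
    return {
        "n_replicates": len(results),
        "bias": float(logs.mean() - beta_true),
        "rmse": float(np.sqrt(np.mean((logs - beta_true) ** 2))),
        "coverage": float(cover.mean()),
    }
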
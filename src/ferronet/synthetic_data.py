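"""Seeded generators for every input the pipeline consumes.

Three worlds are generated, each with its ground truth:

* a replicated two-condition RPKM table with planted up/down genes
  (log-normal baseline, additive log2 effect, i.i.d. log2 noise);
* a log2-scale expression compendium with planted co-expression modules,
  each module an equicorrelated single-factor block so the population
  Pearson correlation between any two members equals ``within_corr``;
* a toy rooted GO DAG with genes annotated to leaves and a study set
  over-sampled for planted leaf terms.

Every generator is a pure function of its config, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .go_enrichment import GoDag
from .io_formats import ExpressionTable

__all__ = [
    "DESimConfig",
    "CompendiumSimConfig",
    "SyntheticTruth",
    "simulate_de_dataset",
    "simulate_compendium",
    "simulate_go_world",
]

MINUS_FE = "minusFe"
PLUS_FE = "plusFe"


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every synthetic dataset."""

    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    module_assignment: dict[str, int] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.de_up & self.de_down:
            raise ValueError("a gene cannot be planted both up and down")


@dataclass
class DESimConfig:
    """Two-condition replicated RPKM simulation.

    Defaults mirror the study design: three biological replicates per
    condition, ~5% of genes responding in each direction with a mean
    |log2 fold change| of 1 against log2-normal noise of 0.25.
    """

    n_genes: int = 1000
    n_reps: int = 3
    frac_up: float = 0.05
    frac_down: float = 0.05
    log2fc_magnitude: float = 1.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (t-test undefined below)")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("frac_up/frac_down must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.log2fc_magnitude <= 0:
            raise ValueError("log2fc_magnitude must be positive")
        if self.noise_log2_sd < 0:
            raise ValueError("noise_log2_sd must be non-negative")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_de_dataset(cfg: DESimConfig) -> tuple[ExpressionTable, SyntheticTruth]:
    """Generate an RPKM table with planted differential expression.

    Per gene g: baseline b_g ~ N(baseline_log2_mean, baseline_log2_sd);
    planted effect +m for up genes, -m for down genes, 0 otherwise.  A
    -Fe replicate is 2^(b_g + delta_g + eps), a +Fe replicate 2^(b_g + eps),
    with eps ~ N(0, noise_log2_sd) drawn independently per cell.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    chosen = rng.choice(cfg.n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = chosen[:n_up], chosen[n_up:]

    delta = np.zeros(cfg.n_genes)
    delta[up_idx] = cfg.log2fc_magnitude
    delta[down_idx] = -cfg.log2fc_magnitude
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    eps_minus = rng.normal(0, cfg.noise_log2_sd, (cfg.n_genes, cfg.n_reps))
    eps_plus = rng.normal(0, cfg.noise_log2_sd, (cfg.n_genes, cfg.n_reps))
    minus = 2.0 ** (baseline[:, None] + delta[:, None] + eps_minus)
    plus = 2.0 ** (baseline[:, None] + eps_plus)

    sample_ids = [f"{MINUS_FE}_r{i + 1}" for i in range(cfg.n_reps)] + [
        f"{PLUS_FE}_r{i + 1}" for i in range(cfg.n_reps)
    ]
    meta = pd.DataFrame(
        {
            "condition": [MINUS_FE] * cfg.n_reps + [PLUS_FE] * cfg.n_reps,
            "replicate": list(range(1, cfg.n_reps + 1)) * 2,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(
        np.hstack([minus, plus]), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    truth = SyntheticTruth(
        de_up={genes[i] for i in up_idx}, de_down={genes[i] for i in down_idx}
    )
    return ExpressionTable(values, "rpkm", meta), truth


@dataclass
class CompendiumSimConfig:
    """Log2-scale array compendium with equicorrelated planted modules.

    ``modules`` lists (size, within_corr) blocks; member genes share one
    latent factor per array so the population pairwise Pearson r equals
    within_corr.  Remaining genes are independent background noise.
    The 300-array default matches the root-compendium scale the module
    analysis is designed around.
    """

    n_genes: int = 1000
    n_arrays: int = 300
    modules: list[tuple[int, float]] = field(default_factory=lambda: [(30, 0.85), (20, 0.85), (10, 0.85)])
    background_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(size for size, _ in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for _, v in self.modules:
            if not 0 < v < 1:
                raise ValueError(f"within_corr must be strictly in (0, 1): {v}")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if self.n_arrays < 2:
            raise ValueError("n_arrays must be >= 2")


def simulate_compendium(cfg: CompendiumSimConfig) -> tuple[ExpressionTable, SyntheticTruth]:
    """Generate the compendium: x_ga = sqrt(v) z_a + sqrt(1-v) eps_ga for
    members of a module with within-correlation v; background genes are
    independent N(0, background_sd)."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    x = rng.normal(0, cfg.background_sd, (cfg.n_genes, cfg.n_arrays))
    assignment: dict[str, int] = {}
    row = 0
    for m, (size, v) in enumerate(cfg.modules):
        z = rng.normal(0, 1, cfg.n_arrays)
        eps = rng.normal(0, 1, (size, cfg.n_arrays))
        x[row : row + size] = np.sqrt(v) * z[None, :] + np.sqrt(1 - v) * eps
        for g in genes[row : row + size]:
            assignment[g] = m
        row += size
    sample_ids = [f"A{i:04d}" for i in range(cfg.n_arrays)]
    meta = pd.DataFrame(
        {"condition": ["compendium"] * cfg.n_arrays, "replicate": list(range(1, cfg.n_arrays + 1))},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return ExpressionTable(values, "log2", meta), SyntheticTruth(module_assignment=assignment)


def simulate_go_world(
    n_genes: int,
    dag_depth: int = 3,
    branching: int = 2,
    planted_terms: set[str] | None = None,
    seed: int = 0,
    n_study: int | None = None,
    enrichment_strength: float = 10.0,
) -> tuple[GoDag, dict[str, frozenset[str]], set[str], SyntheticTruth]:
    """Build a toy GO world: a complete ``branching``-ary tree of depth
    ``dag_depth`` rooted at T0, genes annotated uniformly to leaves, and a
    study set that over-samples genes annotated to ``planted_terms`` with
    the given odds ratio.  Returns (dag, direct annotations, study, truth).
    """
    if dag_depth < 2:
        raise ValueError("dag_depth must be >= 2")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)

    terms = ["T0"]
    edges: list[tuple[str, str]] = []
    frontier = ["T0"]
    counter = 1
    for _ in range(dag_depth):
        nxt = []
        for parent in frontier:
            for _ in range(branching):
                t = f"T{counter}"
                counter += 1
                terms.append(t)
                edges.append((t, parent))
                nxt.append(t)
        frontier = nxt
    dag = GoDag.from_edges(terms, edges, names={t: f"term {t}" for t in terms})
    leaves = sorted(dag.leaves)

    planted = set(planted_terms or ())
    non_leaf = planted - set(leaves)
    if non_leaf:
        raise ValueError(f"planted terms must be leaves: {sorted(non_leaf)}")

    genes = _gene_names(n_genes)
    leaf_idx = rng.integers(0, len(leaves), n_genes)
    direct = {g: frozenset({leaves[i]}) for g, i in zip(genes, leaf_idx)}

    if n_study is None:
        n_study = max(5, n_genes // 10)
    weights = np.ones(n_genes)
    for j, g in enumerate(genes):
        if direct[g] & planted:
            weights[j] = enrichment_strength
    weights /= weights.sum()
    study_idx = rng.choice(n_genes, size=min(n_study, n_genes), replace=False, p=weights)
    study = {genes[i] for i in study_idx}

    truth = SyntheticTruth(enriched_terms=planted)
    return dag, direct, study, truth
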
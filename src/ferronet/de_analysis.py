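"""Response-ratio differential expression for the -Fe/+Fe contrast.

Each gene's response ratio is its -Fe transcript level divided by its
+Fe level, computed per biological replicate (replicates are paired by
index), summarised by the arithmetic mean and the n-1 standard
deviation, and tested with a Student t-test on log2-transformed values
(two-sample equal-variance by default; a paired one-sample test on the
log ratios is available via ``DEFilterConfig.test``).  Genes pass the
fold-change filter when the mean ratio is >= the threshold (up) or
<= its reciprocal (down) and the p-value is <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionTable, GeneAnnotationTable, normalize_gene_id

__all__ = [
    "RatioRecord",
    "DEFilterConfig",
    "DEGeneSet",
    "compute_ratio_records",
    "filter_de",
    "subfamily_summary",
    "merge_gene_sets",
    "load_table1_pk",
    "load_table2_pp",
    "records_from_annotation",
]


@dataclass
class RatioRecord:
    """Per-gene -Fe/+Fe statistics.

    ``ratios`` holds the per-replicate response ratios when replicate
    data exist; records transcribed from printed tables carry mean/SD
    only (ratios=None) with p_value 0.0 as a "already passed P<0.05"
    sentinel.
    """

    gene_id: str
    ratios: list[float] | None
    mean_ratio: float
    sd_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        self.gene_id = normalize_gene_id(self.gene_id)
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"{self.gene_id}: p_value outside [0, 1]")
        if self.ratios is not None:
            if not np.isclose(self.mean_ratio, float(np.mean(self.ratios))):
                raise ValueError(f"{self.gene_id}: mean_ratio != mean(ratios)")


@dataclass
class DEFilterConfig:
    """Significance and fold-change thresholds.

    alpha 0.05 and fold-change cutoffs of 1.2 / 1.5 are the conventional
    values for this contrast; the pseudocount guards ratios against
    near-zero +Fe denominators and is set to 0 for noise-free fixtures.
    """

    alpha: float = 0.05
    fc_threshold: float = 1.5
    pseudocount: float = 0.01
    test: str = "two_sample"  # or "one_sample" (paired, on log2 ratios)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.test not in ("two_sample", "one_sample"):
            raise ValueError(f"unknown test {self.test!r}")


def compute_ratio_records(
    table: ExpressionTable,
    cfg: DEFilterConfig | None = None,
    minus_label: str = "minusFe",
    plus_label: str = "plusFe",
) -> list[RatioRecord]:
    """Per-replicate ratios, their mean/SD, and a t-test p-value per gene."""
    cfg = cfg or DEFilterConfig()
    if table.scale != "rpkm":
        raise ValueError("ratio records require an rpkm-scale table")
    minus = table.samples_for(minus_label)
    plus = table.samples_for(plus_label)
    if minus.shape[1] == 0 or plus.shape[1] == 0:
        raise ValueError(
            f"conditions {minus_label!r}/{plus_label!r} not found in sample metadata"
        )
    if minus.shape[1] != plus.shape[1]:
        raise ValueError(
            f"unmatched replicate structure: {minus.shape[1]} {minus_label} vs "
            f"{plus.shape[1]} {plus_label} samples"
        )
    if minus.shape[1] < 2:
        raise ValueError("need at least 2 replicates per condition for a t-test")

    m = minus.to_numpy() + cfg.pseudocount
    p = plus.to_numpy() + cfg.pseudocount
    ratios = m / p
    mean = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1)
    log_m, log_p = np.log2(m), np.log2(p)
    if cfg.test == "two_sample":
        res = stats.ttest_ind(log_m, log_p, axis=1, equal_var=True)
        pvals = res.pvalue
    else:
        res = stats.ttest_1samp(log_m - log_p, 0.0, axis=1)
        pvals = res.pvalue
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance genes: no evidence

    return [
        RatioRecord(
            gene_id=g,
            ratios=list(ratios[i]),
            mean_ratio=float(mean[i]),
            sd_ratio=float(sd[i]),
            p_value=float(pvals[i]),
        )
        for i, g in enumerate(table.gene_ids)
    ]


@dataclass
class DEGeneSet:
    up: set[str]
    down: set[str]
    fc_threshold: float
    alpha: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def all_genes(self) -> set[str]:
        return self.up | self.down


def filter_de(records: list[RatioRecord], cfg: DEFilterConfig | None = None) -> DEGeneSet:
    """Split records into up (mean >= fc) and down (mean <= 1/fc) at p <= alpha."""
    cfg = cfg or DEFilterConfig()
    up: set[str] = set()
    down: set[str] = set()
    for rec in records:
        if rec.mean_ratio <= 0:
            raise ValueError(f"{rec.gene_id}: non-positive mean ratio")
        if rec.p_value > cfg.alpha:
            continue
        if rec.mean_ratio >= cfg.fc_threshold:
            up.add(rec.gene_id)
        elif rec.mean_ratio <= 1.0 / cfg.fc_threshold:
            down.add(rec.gene_id)
    return DEGeneSet(up=up, down=down, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha)


def subfamily_summary(
    genes: set[str],
    annot: GeneAnnotationTable,
    groups: dict[str, set[str]],
) -> dict[str, int]:
    """Count genes per subfamily group; unmatched genes land in 'other'."""
    sub = dict(zip(annot.df["gene_id"], annot.df["subfamily"]))
    counts = {label: 0 for label in groups}
    counts["other"] = 0
    for g in sorted(normalize_gene_id(x) for x in genes):
        if g not in sub:
            raise KeyError(f"gene {g!r} missing from annotation table")
        for label, members in groups.items():
            if sub[g] in members:
                counts[label] += 1
                break
        else:
            counts["other"] += 1
    return counts


def merge_gene_sets(set_a, set_b) -> tuple[set[str], set[str]]:
    """Case-insensitive union and intersection of two gene-ID sets."""
    a = {normalize_gene_id(g) for g in set_a}
    b = {normalize_gene_id(g) for g in set_b}
    return a | b, a & b


# annotated with both kinase and phosphatase activity; counted once in unions
DUAL_ACTIVITY_GENES = frozenset({"AT2G46700", "AT3G49370"})


def _load_fixture(name: str, subfamily_col: str) -> tuple[list[RatioRecord], GeneAnnotationTable, pd.DataFrame]:
    with resources.files("ferronet.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
    df[subfamily_col] = df.get(subfamily_col, pd.Series(dtype=str)).fillna("")
    records = [
        RatioRecord(
            gene_id=row["gene_id"],
            ratios=None,
            mean_ratio=float(row["mean_ratio"]),
            sd_ratio=float(row["sd_ratio"]),
            p_value=0.0,  # table rows were pre-filtered at P < 0.05
        )
        for _, row in df.iterrows()
    ]
    cls = "kinase" if subfamily_col == "subfamily" else "phosphatase"
    classes = [
        "both" if normalize_gene_id(g) in DUAL_ACTIVITY_GENES else cls
        for g in df["gene_id"]
    ]
    annot = GeneAnnotationTable(
        pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "function": df["function"],
                "class": classes,
                "subfamily": df[subfamily_col],
            }
        )
    )
    return records, annot, df


def load_table1_pk() -> tuple[list[RatioRecord], GeneAnnotationTable]:
    """The 53 Fe-responsive protein-kinase genes (>1.5-fold), transcribed."""
    records, annot, _ = _load_fixture("table1_pk.tsv", "subfamily")
    return records, annot


def load_table2_pp() -> tuple[list[RatioRecord], GeneAnnotationTable]:
    """The 7 Fe-responsive protein-phosphatase genes (>1.5-fold), transcribed."""
    records, annot, _ = _load_fixture("table2_pp.tsv", "alias")
    return records, annot


def records_from_annotation(df: pd.DataFrame) -> list[RatioRecord]:
    """Build sentinel RatioRecords (p=0) from a mean/SD-only table."""
    return [
        RatioRecord(row["gene_id"], None, float(row["mean_ratio"]), float(row["sd_ratio"]), 0.0)
        for _, row in df.iterrows()
    ]
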
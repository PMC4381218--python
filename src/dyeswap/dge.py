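"""Dye-swap combination, per-gene replicate-spot statistics and DEG calling.

Each condition is measured on a pair of slides with reversed Cy3/Cy5
assignment.  After orientation-resolved preprocessing, the M values of the
two slides are directly poolable: a gene retained on both slides contributes
up to 12 replicate spots (6 per slide).  Differential expression is assessed
per gene by a one-sample two-sided Student t test of the mean log2
expression ratio against zero, with no moderation and no multiple-testing
adjustment, and a gene is called differentially expressed when p < 0.01 and
the linear fold change is at least 1.5 in either direction.

Fold changes use the sign-magnitude convention common in two-color array
reports: mean log2 ER m maps to 2**m for m >= 0 and to -2**(-m) for m < 0,
so a 74.5-fold down-regulation reads -74.54 rather than 0.0134.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ParameterError
from .preprocess import RatioSet

STAT_COLUMNS = ["gene", "gene_name", "n", "mean_log2er", "t", "p", "fc",
                "direction", "is_deg", "degenerate"]


@dataclass
class GeneReplicateMatrix:
    """Per-gene vectors of orientation-aligned normalized log2 ER values
    pooled across the two slides of a dye-swap pair."""

    condition_id: str
    values: dict[str, np.ndarray]
    gene_names: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.values)


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


@dataclass
class DEGTable:
    """Per-condition gene statistics plus the subset called differential."""

    condition_id: str
    stats: pd.DataFrame           # all analyzable genes, STAT_COLUMNS
    p_threshold: float
    fc_threshold: float

    @property
    def degs(self) -> pd.DataFrame:
        return self.stats[self.stats["is_deg"]]

    @property
    def deg_genes(self) -> set[str]:
        return set(self.degs["gene"])

    @property
    def counts(self) -> tuple[int, int, int]:
        """(total, up, down) among called DEGs."""
        d = self.degs
        up = int((d["direction"] == "up").sum())
        down = int((d["direction"] == "down").sum())
        return up + down, up, down


@dataclass
class VennPartition:
    """Two-way partition of DEG sets from two conditions."""

    only_a: set[str]
    only_b: set[str]
    common: set[str]
    label_a: str = "A"
    label_b: str = "B"
    common_detail: pd.DataFrame | None = None
    excluded: set[str] = field(default_factory=set)

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.only_a), len(self.only_b), len(self.common)


def combine_dye_swap(first: RatioSet, second: RatioSet,
                     min_spots_per_slide: int = 3) -> GeneReplicateMatrix:
    """Pool the normalized M values of a dye-swap pair per gene.

    Both slides must belong to the same condition and have opposite dye
    orientations.  A gene is retained only if it carries at least
    ``min_spots_per_slide`` surviving spots on *each* slide; orientation
    was already resolved when the log ratios were computed, so values are
    concatenated as-is.
    """
    if first.condition_id != second.condition_id:
        raise DesignError(
            f"cannot pair slides from different conditions "
            f"({first.condition_id!r} vs {second.condition_id!r})")
    if first.dye_orientation == second.dye_orientation:
        raise DesignError(
            f"condition {first.condition_id}: both slides have dye "
            f"orientation {first.dye_orientation!r}; a dye-swap pair needs "
            "opposite orientations")
    values: dict[str, np.ndarray] = {}
    names: dict[str, str] = {}
    g1 = {g: sub for g, sub in first.data.groupby("CLONE_ID", sort=False)}
    g2 = {g: sub for g, sub in second.data.groupby("CLONE_ID", sort=False)}
    for gene in first.data["CLONE_ID"].unique():
        if gene not in g2:
            continue
        m1 = g1[gene]["M"].to_numpy(dtype=float)
        m2 = g2[gene]["M"].to_numpy(dtype=float)
        if len(m1) < min_spots_per_slide or len(m2) < min_spots_per_slide:
            continue
        values[gene] = np.concatenate([m1, m2])
        names[gene] = str(g1[gene]["GENE"].iloc[0])
    return GeneReplicateMatrix(condition_id=first.condition_id,
                               values=values, gene_names=names)


def gene_t_test(values: np.ndarray) -> TTestResult:
    """One-sample two-sided Student t test of the mean against zero.

    Degenerate zero-variance vectors cannot support a t statistic; by
    documented convention they return p = 0 when the (exactly repeated)
    value is nonzero and p = 1 when it is zero, with ``degenerate`` set.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ParameterError("gene_t_test needs at least 2 replicate values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=math.copysign(math.inf, mean), p=0.0,
                           degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, p=p)


def fold_change(mean_log2er: float) -> float:
    """Sign-magnitude linear fold change of a mean log2 expression ratio."""
    if not math.isfinite(mean_log2er):
        raise ParameterError("mean log2 ER must be finite")
    if mean_log2er >= 0:
        return 2.0 ** mean_log2er
    return -(2.0 ** (-mean_log2er))


def log2er_from_fold_change(fc: float) -> float:
    """Inverse of :func:`fold_change`; |fc| must be >= 1."""
    if abs(fc) < 1.0:
        raise ParameterError(f"sign-magnitude fold change has |fc| >= 1, "
                             f"got {fc}")
    return math.log2(fc) if fc >= 1 else -math.log2(-fc)


def gene_statistics(matrix: GeneReplicateMatrix) -> pd.DataFrame:
    """Per-gene mean log2 ER, t statistic, p value and fold change."""
    rows = []
    for gene, vals in matrix.values.items():
        res = gene_t_test(vals)
        mean = float(np.mean(vals))
        rows.append({
            "gene": gene,
            "gene_name": matrix.gene_names.get(gene, gene),
            "n": len(vals),
            "mean_log2er": mean,
            "t": res.t,
            "p": res.p,
            "fc": fold_change(mean),
            "direction": "up" if mean >= 0 else "down",
            "is_deg": False,
            "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def call_degs(stats_df: pd.DataFrame, condition_id: str,
              p_threshold: float = 0.01, fc_threshold: float = 1.5
              ) -> DEGTable:
    """Flag genes with p below threshold and |fold change| at or above
    threshold.  ``fc_threshold=1.0`` disables the fold-change filter."""
    if not 0 < p_threshold <= 1:
        raise ParameterError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if fc_threshold < 1:
        raise ParameterError(f"fc_threshold must be >= 1, got {fc_threshold}")
    df = stats_df.copy()
    df["is_deg"] = (df["p"] < p_threshold) & (df["fc"].abs() >= fc_threshold)
    return DEGTable(condition_id=condition_id, stats=df,
                    p_threshold=p_threshold, fc_threshold=fc_threshold)


def compare_conditions(a: DEGTable, b: DEGTable) -> VennPartition:
    """Partition two conditions' DEG sets into exclusive and shared genes.

    Genes analyzable in only one of the two conditions cannot be classified
    and are excluded from the comparison (reported in ``excluded``).  Shared
    DEGs are annotated with both fold changes and a same-direction flag.
    """
    universe_a = set(a.stats["gene"])
    universe_b = set(b.stats["gene"])
    shared_universe = universe_a & universe_b
    excluded = ((a.deg_genes | b.deg_genes)
                - ((a.deg_genes | b.deg_genes) & shared_universe))
    set_a = a.deg_genes & shared_universe
    set_b = b.deg_genes & shared_universe
    common = set_a & set_b
    fc_a = a.stats.set_index("gene")["fc"]
    fc_b = b.stats.set_index("gene")["fc"]
    detail = pd.DataFrame({
        "gene": sorted(common),
        "fc_a": [fc_a[g] for g in sorted(common)],
        "fc_b": [fc_b[g] for g in sorted(common)],
    })
    detail["same_direction"] = np.sign(detail["fc_a"]) == np.sign(detail["fc_b"])
    return VennPartition(only_a=set_a - common, only_b=set_b - common,
                         common=common, label_a=a.condition_id,
                         label_b=b.condition_id, common_detail=detail,
                         excluded=excluded)
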
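"""Gene Ontology category statistics for DEG lists.

Two complementary category-level statistics are provided:

* an over-representation test — a 2x2 contingency table (DEG / non-DEG x
  in / out of category) over the analyzable background, evaluated by the
  chi-square test with Yates continuity correction (df = 1, two-sided);
* a rank-based class statistic — up- and down-regulated genes are ranked
  separately by log2 ER magnitude (rank 1 = strongest change, ties share
  the average rank) and member ranks are compared with non-member ranks by
  a two-sample Student t test, a normal-approximation analogue of a
  rank-sum test.

The background universe is the set of genes that survived quality control
in the condition under study, not the full printed platform: enrichment
must condition on what was analyzable.  Category-level summaries report
the arithmetic mean sign-magnitude fold change of member DEGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dge import DEGTable
from .errors import ParameterError


@dataclass
class CategoryEnrichment:
    """Yates-corrected chi-square over-representation result."""

    category_id: str
    label: str
    tgc: int                  # total analyzable genes in the category
    k_deg: int                # DEGs in the category
    n_deg: int                # DEGs in the background
    n_background: int
    chi2_yates: float
    p: float
    significant: bool
    degenerate: bool = False


@dataclass
class CategoryRankStat:
    """Rank-based class statistic for one direction (up or down)."""

    category_id: str
    direction: str
    n_members: int
    n_nonmembers: int
    mean_rank_members: float
    mean_rank_nonmembers: float
    t: float
    p: float
    significant: bool
    degenerate: bool = False


@dataclass
class CategoryFCSummary:
    """Mean sign-magnitude fold change of a category's member DEGs."""

    category_id: str
    mean_fc: float
    n: int
    bidirectional: bool


def yates_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and p value for a 2x2 table.

    Delegates to :func:`scipy.stats.chi2_contingency` with continuity
    correction; the correction shifts each cell half a count toward its
    expectation, clipping at the expectation, which for a 2x2 table equals
    the classical N(max(|ad - bc| - N/2, 0))^2 / (row and column products)
    formula.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


def overrepresentation_test(deg_set: set[str], background_set: set[str],
                            members: set[str], category_id: str,
                            label: str | None = None,
                            alpha: float = 0.05) -> CategoryEnrichment:
    """Test whether a category is over-represented among DEGs.

    The category member set is intersected with the background before the
    table is built.  A table with any zero margin carries no information
    about association; it is reported with p = 1 and the degenerate flag.
    """
    if not deg_set <= background_set:
        raise ParameterError("deg_set must be a subset of background_set")
    mem = members & background_set
    n = len(background_set)
    a = len(deg_set & mem)                  # DEG, in category
    b = len(deg_set) - a                    # DEG, out of category
    c = len(mem) - a                        # non-DEG, in category
    d = n - a - b - c                       # non-DEG, out of category
    degenerate = (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0)
    if degenerate:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = yates_chi2(a, b, c, d)
    return CategoryEnrichment(category_id=category_id,
                              label=label or category_id,
                              tgc=len(mem), k_deg=a, n_deg=len(deg_set),
                              n_background=n, chi2_yates=chi2, p=p,
                              significant=(not degenerate) and p < alpha,
                              degenerate=degenerate)


def rank_category_test(gene_stats: pd.DataFrame, members: set[str],
                       category_id: str, direction: str,
                       alpha: float = 0.05) -> CategoryRankStat:
    """Compare member vs non-member ranks in one directional gene list.

    Genes whose mean log2 ER has the requested sign are ranked by magnitude
    (rank 1 = largest |log2 ER|, average ranks on ties); member and
    non-member ranks are then compared with a two-sample Student t test.
    Depends on the log2 ER values only through their ranks.
    """
    if direction not in ("up", "down"):
        raise ParameterError(f"direction must be 'up' or 'down', got "
                             f"{direction!r}")
    sub = gene_stats[gene_stats["direction"] == direction]
    genes = sub["gene"].to_numpy()
    magnitude = sub["mean_log2er"].abs().to_numpy(dtype=float)
    # rank 1 = largest magnitude; scipy ranks ascending, so rank the negation
    ranks = stats.rankdata(-magnitude, method="average")
    is_member = np.array([g in members for g in genes])
    n_mem = int(is_member.sum())
    n_non = int((~is_member).sum())
    if n_mem < 2 or n_non < 2:
        return CategoryRankStat(category_id=category_id, direction=direction,
                                n_members=n_mem, n_nonmembers=n_non,
                                mean_rank_members=float("nan"),
                                mean_rank_nonmembers=float("nan"),
                                t=float("nan"), p=1.0, significant=False,
                                degenerate=True)
    r_mem = ranks[is_member]
    r_non = ranks[~is_member]
    t, p = stats.ttest_ind(r_mem, r_non, equal_var=True)
    return CategoryRankStat(category_id=category_id, direction=direction,
                            n_members=n_mem, n_nonmembers=n_non,
                            mean_rank_members=float(np.mean(r_mem)),
                            mean_rank_nonmembers=float(np.mean(r_non)),
                            t=float(t), p=float(p),
                            significant=float(p) < alpha)


def category_mean_fc(deg_table: DEGTable, members: set[str],
                     category_id: str) -> CategoryFCSummary | None:
    """Arithmetic mean sign-magnitude fold change of member DEGs.

    Returns None when the category has no member DEGs (absent from the
    report).  A category whose members change in both directions is
    flagged bidirectional, since opposite signs cancel in the mean.
    """
    degs = deg_table.degs
    sub = degs[degs["gene"].isin(members)]
    if len(sub) == 0:
        return None
    fcs = sub["fc"].to_numpy(dtype=float)
    return CategoryFCSummary(category_id=category_id,
                             mean_fc=float(np.mean(fcs)), n=len(sub),
                             bidirectional=bool((fcs > 0).any()
                                                and (fcs < 0).any()))


def enrichment_report(deg_table: DEGTable,
                      categories: dict[str, tuple[str, frozenset[str]]],
                      alpha: float = 0.05,
                      bh_adjust: bool = False) -> pd.DataFrame:
    """Full per-category report for one condition.

    One row per category: TGC, member DEG count, Yates chi-square p, the
    directional rank-test p values, and the mean member-DEG fold change.
    ``bh_adjust`` optionally applies Benjamini-Hochberg across categories
    to the chi-square p values (off by default; the headline statistics are
    per-category).
    """
    background = set(deg_table.stats["gene"])
    deg_set = deg_table.deg_genes
    rows = []
    for cat_id, (label, members) in sorted(categories.items()):
        enr = overrepresentation_test(deg_set, background, set(members),
                                      cat_id, label, alpha=alpha)
        rank_up = rank_category_test(deg_table.stats, set(members), cat_id,
                                     "up", alpha=alpha)
        rank_down = rank_category_test(deg_table.stats, set(members), cat_id,
                                       "down", alpha=alpha)
        fc = category_mean_fc(deg_table, set(members), cat_id)
        rows.append({
            "category": cat_id, "label": label, "tgc": enr.tgc,
            "k_deg": enr.k_deg, "chi2_yates": enr.chi2_yates,
            "p_chi": enr.p, "significant": enr.significant,
            "p_rank_up": rank_up.p, "p_rank_down": rank_down.p,
            "mean_fc_degs": fc.mean_fc if fc else float("nan"),
            "n_fc_degs": fc.n if fc else 0,
        })
    report = pd.DataFrame(rows)
    if bh_adjust and len(report):
        from statsmodels.stats.multitest import multipletests
        rej, adj, _, _ = multipletests(report["p_chi"], alpha=alpha,
                                       method="fdr_bh")
        report["p_chi_bh"] = adj
        report["significant"] = rej
    return report
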
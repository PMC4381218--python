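"""Spot quality filtering, expression-ratio computation and lowess normalization.

The quality filter applies the two signal-quality criteria per channel —
signal-to-background ratio I/B >= 3 and contrast (I - B)/(SI + SB) >= 0.6 —
drops scanner-flagged spots and spots whose background-subtracted intensity
is non-positive in either channel (their log ratio is undefined), and then
discards any gene left with fewer than three high-quality spots on a slide.

Expression ratios are carried in MA coordinates: per spot,
``A = (log2(I1 - B1) + log2(I2 - B2)) / 2`` and ``M = log2 ER`` with the
test channel resolved from the slide's dye orientation, so that positive M
always means up in the treated sample regardless of which dye carried it.

Normalization subtracts intensity-dependent bias with robust lowess in
(A, M) space: one pass over the whole slide, then one pass per meta-row
group, then one per meta-column group (or one pass per print block in
``blocks`` mode).  Groups too small to support a local fit keep the
global correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .array_io import SlideScan
from .errors import IntegrityError, ParameterError

RATIO_COLUMNS = ["CLONE_ID", "GENE", "BLOCK_ROW", "BLOCK_COL", "REP",
                 "A", "M_raw", "M"]

STAGES = ("raw", "slide_normalized", "block_normalized")


@dataclass
class QualityVerdict:
    """Per-spot quality assessment: the two criteria per channel plus the
    overall verdict (both criteria in both channels, not flagged, positive
    background-subtracted signal)."""

    ratio_ib: tuple[float, float]
    contrast: tuple[float, float]
    passed: bool


@dataclass
class FilterReport:
    """What the filter removed and why."""

    n_spots_in: int
    n_spots_failed: int
    removed_genes: dict[str, str] = field(default_factory=dict)
    surviving_spot_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class RatioSet:
    """Per-spot MA values for the surviving spots of one slide.

    ``data`` columns: CLONE_ID, GENE, BLOCK_ROW, BLOCK_COL, REP, A, M_raw, M.
    ``stage`` tracks how far normalization has progressed; ``curves`` holds
    the fitted lowess curves (label -> DataFrame of A, fitted) for MA-plot
    diagnostics.
    """

    slide_id: str
    condition_id: str
    dye_orientation: str
    data: pd.DataFrame
    meta_grid: tuple[int, int]
    stage: str = "raw"
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def _criteria(i, b, si, sb):
    """Vectorized evaluation of the two quality criteria for one channel.

    Returns (ratio, contrast, ok).  Zero background: the ratio criterion
    passes iff I > 0 (infinite ratio), fails for an all-zero spot.  A zero
    noise denominator passes the contrast criterion iff I - B > 0.
    """
    i = np.asarray(i, dtype=float)
    b = np.asarray(b, dtype=float)
    si = np.asarray(si, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if (i < 0).any() or (b < 0).any() or (si < 0).any() or (sb < 0).any():
        raise IntegrityError("negative intensity passed to quality filter")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, i / np.where(b > 0, b, 1.0),
                         np.where(i > 0, np.inf, 0.0))
        denom = si + sb
        contrast = np.where(denom > 0, (i - b) / np.where(denom > 0, denom, 1.0),
                            np.where(i - b > 0, np.inf, -np.inf))
    return ratio, contrast


def spot_quality(spot, t_ratio: float = 3.0, t_contrast: float = 0.6
                 ) -> QualityVerdict:
    """Assess a single spot (a mapping with the slide-scan column names)."""
    if t_ratio <= 0 or t_contrast <= 0:
        raise ParameterError("quality thresholds must be > 0")
    r1, c1 = _criteria(spot["F1_MED"], spot["B1_MED"],
                       spot["F1_SD"], spot["B1_SD"])
    r2, c2 = _criteria(spot["F2_MED"], spot["B2_MED"],
                       spot["F2_SD"], spot["B2_SD"])
    pos = (spot["F1_MED"] > spot["B1_MED"]) and (spot["F2_MED"] > spot["B2_MED"])
    passed = bool(r1 >= t_ratio and r2 >= t_ratio
                  and c1 >= t_contrast and c2 >= t_contrast
                  and not bool(spot["FLAG"]) and pos)
    return QualityVerdict(ratio_ib=(float(r1), float(r2)),
                          contrast=(float(c1), float(c2)), passed=passed)


def quality_mask(spots: pd.DataFrame, t_ratio: float = 3.0,
                 t_contrast: float = 0.6) -> np.ndarray:
    """Vectorized spot_quality over a spot table; returns a boolean mask."""
    if t_ratio <= 0 or t_contrast <= 0:
        raise ParameterError("quality thresholds must be > 0")
    r1, c1 = _criteria(spots["F1_MED"], spots["B1_MED"],
                       spots["F1_SD"], spots["B1_SD"])
    r2, c2 = _criteria(spots["F2_MED"], spots["B2_MED"],
                       spots["F2_SD"], spots["B2_SD"])
    pos = ((spots["F1_MED"].to_numpy() > spots["B1_MED"].to_numpy())
           & (spots["F2_MED"].to_numpy() > spots["B2_MED"].to_numpy()))
    flagged = spots["FLAG"].to_numpy() != 0
    return ((r1 >= t_ratio) & (r2 >= t_ratio)
            & (c1 >= t_contrast) & (c2 >= t_contrast)
            & ~flagged & pos)


def filter_slide(slide: SlideScan, t_ratio: float = 3.0,
                 t_contrast: float = 0.6, min_spots: int = 3
                 ) -> tuple[SlideScan, FilterReport]:
    """Remove low-quality spots, then genes with < ``min_spots`` survivors.

    Returns the filtered slide and a report listing removed genes with the
    reason (all spots failed vs too few survivors) and per-gene surviving
    spot counts.
    """
    mask = quality_mask(slide.spots, t_ratio, t_contrast)
    kept = slide.spots.loc[mask]
    counts = kept.groupby("CLONE_ID").size()
    good_genes = set(counts[counts >= min_spots].index)
    report = FilterReport(n_spots_in=len(slide.spots),
                          n_spots_failed=int((~mask).sum()))
    for gene in slide.spots["CLONE_ID"].unique():
        n = int(counts.get(gene, 0))
        if n >= min_spots:
            report.surviving_spot_counts[gene] = n
        elif n == 0:
            report.removed_genes[gene] = "no high-quality spots"
        else:
            report.removed_genes[gene] = (
                f"only {n} high-quality spot(s) (< {min_spots})")
    out = kept[kept["CLONE_ID"].isin(good_genes)].reset_index(drop=True)
    filtered = replace(slide, spots=out)
    return filtered, report


def compute_log_ratios(slide: SlideScan) -> RatioSet:
    """Background-subtract and convert a filtered slide to MA coordinates.

    The test channel is resolved from ``dye_orientation`` here, so the M
    values of both slides of a dye-swap pair are directly comparable with
    no later sign flip.
    """
    s = slide.spots
    net1 = s["F1_MED"].to_numpy() - s["B1_MED"].to_numpy()
    net2 = s["F2_MED"].to_numpy() - s["B2_MED"].to_numpy()
    if (net1 <= 0).any() or (net2 <= 0).any():
        raise IntegrityError(
            f"slide {slide.slide_id}: non-positive background-subtracted "
            "intensity; run filter_slide first")
    l1 = np.log2(net1)
    l2 = np.log2(net2)
    a = (l1 + l2) / 2.0
    m = l2 - l1 if slide.dye_orientation == "test_ch2" else l1 - l2
    data = pd.DataFrame({
        "CLONE_ID": s["CLONE_ID"].to_numpy(),
        "GENE": s["GENE"].to_numpy(),
        "BLOCK_ROW": s["BLOCK_ROW"].to_numpy(),
        "BLOCK_COL": s["BLOCK_COL"].to_numpy(),
        "REP": s["REP"].to_numpy(),
        "A": a, "M_raw": m, "M": m,
    })
    return RatioSet(slide_id=slide.slide_id, condition_id=slide.condition_id,
                    dye_orientation=slide.dye_orientation, data=data,
                    meta_grid=slide.meta_grid, stage="raw")


def _lowess_fit(a: np.ndarray, m: np.ndarray, span: float,
                robust_iters: int) -> np.ndarray:
    """Robust lowess fitted values of m on a, in input order."""
    if len(np.unique(a)) < 2:
        return np.full_like(m, float(np.mean(m)))
    return _sm_lowess(m, a, frac=span, it=robust_iters, return_sorted=False)


def normalize_lowess(ratios: RatioSet, span: float = 0.3,
                     robust_iters: int = 3, min_group: int = 20,
                     mode: str = "marginal") -> RatioSet:
    """Subtract intensity-dependent and spatial bias with sequential lowess.

    Pass 1 fits M on A over the whole slide and subtracts the fit.  In
    ``marginal`` mode (the default) pass 2 refits the residual within each
    meta-row group and pass 3 within each meta-column group; in ``blocks``
    mode a single second pass fits within each (row, col) print block.
    Groups smaller than ``min_group`` spots retain the global correction
    only.  Membership never changes — only M values do.
    """
    if not 0 < span <= 1:
        raise ParameterError(f"span must be in (0, 1], got {span}")
    if robust_iters < 0:
        raise ParameterError("robust_iters must be >= 0")
    if mode not in ("marginal", "blocks"):
        raise ParameterError(f"unknown normalization mode {mode!r}")
    df = ratios.data.copy()
    a = df["A"].to_numpy(dtype=float)
    m = df["M_raw"].to_numpy(dtype=float).copy()
    curves: dict[str, pd.DataFrame] = {}

    fit = _lowess_fit(a, m, span, robust_iters)
    curves["slide"] = _curve_frame(a, fit)
    m = m - fit

    if mode == "marginal":
        group_specs = ([("row", "BLOCK_ROW", v)
                        for v in range(1, ratios.meta_grid[0] + 1)]
                       + [("col", "BLOCK_COL", v)
                          for v in range(1, ratios.meta_grid[1] + 1)])
    else:
        group_specs = [("block", ("BLOCK_ROW", "BLOCK_COL"), (r, c))
                       for r in range(1, ratios.meta_grid[0] + 1)
                       for c in range(1, ratios.meta_grid[1] + 1)]

    for kind, cols, value in group_specs:
        if kind == "block":
            idx = ((df["BLOCK_ROW"].to_numpy() == value[0])
                   & (df["BLOCK_COL"].to_numpy() == value[1]))
            label = f"block_{value[0]}_{value[1]}"
        else:
            idx = df[cols].to_numpy() == value
            label = f"{kind}_{value}"
        n = int(idx.sum())
        if n == 0:
            continue
        if n < min_group:
            curves[label] = pd.DataFrame({"A": [], "fitted": []})
            continue
        fit = _lowess_fit(a[idx], m[idx], span, robust_iters)
        curves[label] = _curve_frame(a[idx], fit)
        m[idx] = m[idx] - fit

    df["M"] = m
    return RatioSet(slide_id=ratios.slide_id, condition_id=ratios.condition_id,
                    dye_orientation=ratios.dye_orientation, data=df,
                    meta_grid=ratios.meta_grid, stage="block_normalized",
                    curves=curves)


def _curve_frame(a: np.ndarray, fitted: np.ndarray) -> pd.DataFrame:
    order = np.argsort(a, kind="stable")
    return pd.DataFrame({"A": a[order], "fitted": fitted[order]})


def write_ratio_set(ratios: RatioSet, path, float_format: str = "%.10g"
                    ) -> str:
    """Diagnostics writer: per-slide TSV of MA values (raw and normalized),
    with the slide metadata in ``# key=value`` comment lines."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# slide_id={ratios.slide_id}\n")
        fh.write(f"# condition_id={ratios.condition_id}\n")
        fh.write(f"# dye_orientation={ratios.dye_orientation}\n")
        fh.write(f"# meta_grid={ratios.meta_grid[0]}x{ratios.meta_grid[1]}\n")
        fh.write(f"# stage={ratios.stage}\n")
        ratios.data[RATIO_COLUMNS].to_csv(fh, sep="\t", index=False,
                                          float_format=float_format,
                                          lineterminator="\n")
    return str(path)


def read_ratio_set(path) -> RatioSet:
    """Read a ratio-set TSV written by :func:`write_ratio_set`."""
    import io as _io

    from .array_io import _parse_metadata
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    meta = _parse_metadata([ln for ln in lines if ln.startswith("#")],
                           str(path))
    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    df = pd.read_csv(_io.StringIO(body), sep="\t",
                     dtype={"CLONE_ID": str, "GENE": str})
    grid = tuple(int(x) for x in meta["meta_grid"].lower().split("x"))
    return RatioSet(slide_id=meta["slide_id"],
                    condition_id=meta["condition_id"],
                    dye_orientation=meta["dye_orientation"],
                    data=df[RATIO_COLUMNS],
                    meta_grid=(grid[0], grid[1]),
                    stage=meta.get("stage", "raw"))


def preprocess_slide(slide: SlideScan, t_ratio: float = 3.0,
                     t_contrast: float = 0.6, min_spots: int = 3,
                     span: float = 0.3, robust_iters: int = 3,
                     min_group: int = 20, mode: str = "marginal"
                     ) -> tuple[RatioSet, FilterReport]:
    """Filter -> log ratios -> lowess normalization for one slide."""
    filtered, report = filter_slide(slide, t_ratio, t_contrast, min_spots)
    ratios = compute_log_ratios(filtered)
    normalized = normalize_lowess(ratios, span=span, robust_iters=robust_iters,
                                  min_group=min_group, mode=mode)
    return normalized, report
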
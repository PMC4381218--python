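"""Readers and writers for slide scans, platform annotation and experiment manifests.

All files are plain tab-separated text with a documented header.  The slide
scan dialect is GPR-like: one row per spot, two channels (ch1 = Cy3,
ch2 = Cy5), median foreground/background intensities and their standard
deviations, plus the meta-grid coordinates used for spatial normalization.
Slide-level metadata (slide id, condition, dye orientation, grid shape) is
carried in ``# key=value`` comment lines before the header so that a single
file fully describes one hybridization.

The ``dye_orientation`` field records which channel carries the *test*
(treated) sample: ``test_ch2`` means test = Cy5 / control = Cy3 (the first
slide of a dye-swap pair), ``test_ch1`` the reverse (the swap slide).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, IntegrityError

#: Column order of the slide-scan dialect.
SPOT_COLUMNS = [
    "CLONE_ID", "GENE", "BLOCK_ROW", "BLOCK_COL", "REP",
    "F1_MED", "B1_MED", "F1_SD", "B1_SD",
    "F2_MED", "B2_MED", "F2_SD", "B2_SD", "FLAG",
]

_INT_COLUMNS = ["BLOCK_ROW", "BLOCK_COL", "REP", "FLAG"]
_FLOAT_COLUMNS = ["F1_MED", "B1_MED", "F1_SD", "B1_SD",
                  "F2_MED", "B2_MED", "F2_SD", "B2_SD"]

ORIENTATIONS = ("test_ch2", "test_ch1")


@dataclass
class SlideScan:
    """One hybridized array: spot table plus slide-level metadata.

    ``spots`` is a DataFrame with the :data:`SPOT_COLUMNS` columns, one row
    per printed spot.  ``meta_grid`` is the (rows, cols) shape of the
    meta-grid (print-block layout) used by the spatial normalization passes.
    """

    slide_id: str
    condition_id: str
    dye_orientation: str
    spots: pd.DataFrame
    meta_grid: tuple[int, int] = (12, 4)

    def __post_init__(self) -> None:
        if self.dye_orientation not in ORIENTATIONS:
            raise DesignError(
                f"slide {self.slide_id}: dye_orientation must be one of "
                f"{ORIENTATIONS}, got {self.dye_orientation!r}")
        validate_spot_table(self.spots, self.meta_grid, context=self.slide_id)

    @property
    def n_spots(self) -> int:
        return len(self.spots)


@dataclass
class PlatformAnnotation:
    """Platform annotation: clone -> (gene, accession, categories) plus
    category -> (label, member clone set)."""

    clones: dict[str, tuple[str, str, frozenset[str]]]
    categories: dict[str, tuple[str, frozenset[str]]]

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def category_members(self, category_id: str) -> frozenset[str]:
        return self.categories[category_id][1]

    def gene_name(self, clone_id: str) -> str:
        return self.clones[clone_id][0]


@dataclass
class ExperimentDesign:
    """Conditions and their dye-swap slide pairs.

    ``pairs[condition_id]`` is ``(slide_id_test_ch2, slide_id_test_ch1)``:
    the first slide labels test with Cy5, the second is the swap.
    """

    conditions: list[tuple[str, str, int, str]] = field(default_factory=list)
    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def condition_ids(self) -> list[str]:
        return [c[0] for c in self.conditions]


def validate_spot_table(spots: pd.DataFrame, meta_grid: tuple[int, int],
                        context: str = "") -> None:
    """Check spot-table invariants: columns, finite non-negative intensities,
    grid coordinates in range, unique (clone, replicate) keys."""
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise FormatError(f"{context}: missing required column(s) {missing}")
    if len(spots) == 0:
        return
    vals = spots[_FLOAT_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise IntegrityError(f"{context}: non-finite intensity value")
    if (vals < 0).any():
        raise IntegrityError(f"{context}: negative intensity value")
    n_rows, n_cols = meta_grid
    br, bc = spots["BLOCK_ROW"], spots["BLOCK_COL"]
    if ((br < 1) | (br > n_rows)).any() or ((bc < 1) | (bc > n_cols)).any():
        raise IntegrityError(f"{context}: BLOCK_ROW/BLOCK_COL outside the "
                             f"{n_rows}x{n_cols} meta-grid")
    dup = spots.duplicated(subset=["CLONE_ID", "REP"])
    if dup.any():
        key = spots.loc[dup.idxmax(), ["CLONE_ID", "REP"]].tolist()
        raise IntegrityError(f"{context}: duplicate (clone_id, replicate) {key}")


def _parse_metadata(lines: list[str], path: str) -> dict[str, str]:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    for key in ("slide_id", "condition_id", "dye_orientation", "meta_grid"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}=' metadata line")
    return meta


def read_slide_scan(path) -> SlideScan:
    """Read one slide scan from its TSV dialect.

    Malformed numeric cells raise :class:`FormatError` rather than being
    coerced to NaN; missing columns and metadata raise with the offending
    name.  Parsing is locale-independent (decimal point only).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    meta_lines = [ln for ln in lines if ln.startswith("#")]
    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    meta = _parse_metadata(meta_lines, str(path))
    try:
        grid = tuple(int(x) for x in meta["meta_grid"].lower().split("x"))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed meta_grid {meta['meta_grid']!r}") from exc

    # Read everything as text first so that bad numerics raise instead of
    # silently becoming NaN (pandas would treat "NA" as missing).
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str,
                     na_filter=False, keep_default_na=False)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[SPOT_COLUMNS].copy()
    for col in _INT_COLUMNS + _FLOAT_COLUMNS:
        try:
            converted = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: malformed numeric cell in column "
                              f"{col}: {exc}") from exc
        df[col] = (converted.astype(np.int64) if col in _INT_COLUMNS
                   else converted.astype(float))
    return SlideScan(slide_id=meta["slide_id"],
                     condition_id=meta["condition_id"],
                     dye_orientation=meta["dye_orientation"],
                     spots=df.reset_index(drop=True),
                     meta_grid=(grid[0], grid[1]))


def write_slide_scan(slide: SlideScan, path) -> str:
    """Write a slide scan; ``read_slide_scan`` round-trips it field-for-field.

    Floats are written with ``repr`` (shortest round-trip representation),
    so the read-back table is bit-identical.
    """
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# slide_id={slide.slide_id}\n")
        fh.write(f"# condition_id={slide.condition_id}\n")
        fh.write(f"# dye_orientation={slide.dye_orientation}\n")
        fh.write(f"# meta_grid={slide.meta_grid[0]}x{slide.meta_grid[1]}\n")
        slide.spots[SPOT_COLUMNS].to_csv(fh, sep="\t", index=False,
                                         lineterminator="\n")
    return str(path)


def read_annotation(path) -> PlatformAnnotation:
    """Read the platform annotation TSV.

    Columns: CLONE_ID, GENE, ACCESSION, CATEGORIES (semicolon-separated
    category ids, empty for unannotated clones).  Optional ``# category:``
    comment lines map category ids to display labels::

        # category: immune_response=immune response
    """
    labels: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    for line in lines:
        if line.startswith("# category:"):
            body = line[len("# category:"):].strip()
            cat_id, _, label = body.partition("=")
            labels[cat_id.strip()] = label.strip() or cat_id.strip()
    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str,
                     na_filter=False, keep_default_na=False)
    for col in ("CLONE_ID", "GENE", "ACCESSION", "CATEGORIES"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column(s) ['{col}']")
    if df["CLONE_ID"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate CLONE_ID")
    clones: dict[str, tuple[str, str, frozenset[str]]] = {}
    members: dict[str, set[str]] = {}
    for clone_id, gene, acc, cats in zip(df["CLONE_ID"], df["GENE"],
                                         df["ACCESSION"], df["CATEGORIES"]):
        cat_set = frozenset(c for c in cats.split(";") if c)
        clones[clone_id] = (gene, acc, cat_set)
        for cat in cat_set:
            members.setdefault(cat, set()).add(clone_id)
    dangling = set(labels) - set(members)
    if dangling:
        warnings.warn(f"{path}: categories with labels but no members: "
                      f"{sorted(dangling)}", stacklevel=2)
    categories = {cat: (labels.get(cat, cat.replace('_', ' ')),
                        frozenset(mem))
                  for cat, mem in members.items()}
    return PlatformAnnotation(clones=clones, categories=categories)


def write_annotation(annotation: PlatformAnnotation, path) -> str:
    """Write a platform annotation TSV (inverse of :func:`read_annotation`)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for cat_id in sorted(annotation.categories):
            label = annotation.categories[cat_id][0]
            fh.write(f"# category: {cat_id}={label}\n")
        fh.write("CLONE_ID\tGENE\tACCESSION\tCATEGORIES\n")
        for clone_id in annotation.clones:
            gene, acc, cats = annotation.clones[clone_id]
            fh.write(f"{clone_id}\t{gene}\t{acc}\t{';'.join(sorted(cats))}\n")
    return str(path)


def read_manifest(path, known_slide_ids=None) -> ExperimentDesign:
    """Read the experiment manifest TSV.

    Columns: CONDITION_ID, TISSUE, TIMEPOINT_H, TREATMENT, SLIDE_ID,
    DYE_ORIENTATION — one row per slide, two rows (one per orientation) per
    condition.  A condition with anything other than exactly one slide per
    orientation is a design error; slide ids referenced but absent from
    ``known_slide_ids`` (when given) are design errors too.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     na_filter=False, keep_default_na=False)
    required = ["CONDITION_ID", "TISSUE", "TIMEPOINT_H", "TREATMENT",
                "SLIDE_ID", "DYE_ORIENTATION"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["SLIDE_ID"].duplicated().any():
        raise DesignError(f"{path}: duplicate SLIDE_ID")
    if known_slide_ids is not None:
        dangling = set(df["SLIDE_ID"]) - set(known_slide_ids)
        if dangling:
            raise DesignError(f"{path}: manifest references unknown slide "
                              f"id(s) {sorted(dangling)}")
    design = ExperimentDesign()
    for cond_id, group in df.groupby("CONDITION_ID", sort=False):
        if len(group) != 2:
            raise DesignError(f"{path}: condition {cond_id} lists "
                              f"{len(group)} slide(s); exactly 2 required")
        orients = dict(zip(group["DYE_ORIENTATION"], group["SLIDE_ID"]))
        if set(orients) != set(ORIENTATIONS):
            raise DesignError(f"{path}: condition {cond_id} must have one "
                              f"slide per dye orientation, got "
                              f"{sorted(orients)}")
        row = group.iloc[0]
        try:
            timepoint = int(row["TIMEPOINT_H"])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed TIMEPOINT_H "
                              f"{row['TIMEPOINT_H']!r}") from exc
        design.conditions.append((cond_id, row["TISSUE"], timepoint,
                                  row["TREATMENT"]))
        design.pairs[cond_id] = (orients["test_ch2"], orients["test_ch1"])
    return design


def write_manifest(design: ExperimentDesign, path) -> str:
    """Write an experiment manifest TSV (inverse of :func:`read_manifest`)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("CONDITION_ID\tTISSUE\tTIMEPOINT_H\tTREATMENT\t"
                 "SLIDE_ID\tDYE_ORIENTATION\n")
        for cond_id, tissue, timepoint, treatment in design.conditions:
            s1, s2 = design.pairs[cond_id]
            fh.write(f"{cond_id}\t{tissue}\t{timepoint}\t{treatment}\t"
                     f"{s1}\ttest_ch2\n")
            fh.write(f"{cond_id}\t{tissue}\t{timepoint}\t{treatment}\t"
                     f"{s2}\ttest_ch1\n")
    return str(path)
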
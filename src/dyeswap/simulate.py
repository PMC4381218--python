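"""Synthetic two-color microarray and qPCR experiment generator.

Emulates a 1818-clone immunochip-style platform printed with six replicate
spots per clone over a 12 x 4 meta-grid, hybridized as dye-swap pairs for
four conditions ({slow, fast} muscle x {24 h, 72 h} LPS vs saline control,
24 slides in total), with known planted truth so every pipeline stage can
be tested against ground truth without external data.

Spot signal model (log2 scale), per spot of gene g on one slide::

    l_test    = baseline(g) + log2FC(g)/2 + noise
    l_control = baseline(g) - log2FC(g)/2 + noise

with iid Gaussian channel noise of SD spot_sd / sqrt(2), so the per-spot
log ratio has SD ``spot_sd``.  The channel carrying Cy5 (ch2) additionally
receives a smooth intensity-dependent dye bias ``amplitude * sin(A / 2)``
plus per-meta-row and per-meta-column offsets drawn fresh per slide, so
both the global and the spatial lowess passes have real work to do.
Foreground medians are ``2**l + B`` with background B drawn per spot and
channel; the quality-filter statistics (SI, SB) are proportional to the
medians, sized so that every regular spot passes the quality criteria by
construction, while planted low-quality spots violate one criterion each
(low signal-to-background, low contrast, or a scanner flag).

Biological pooling (3 fish per RNA pool) is modeled implicitly: the
generator draws one pooled expression level per condition rather than
per-fish levels, which is all the hybridizations ever see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import (ExperimentDesign, PlatformAnnotation, SlideScan,
                       SPOT_COLUMNS)
from .errors import ParameterError

#: Functional category sizes of the emulated platform annotation.
DEFAULT_CATEGORY_SCHEME: dict[str, int] = {
    "immune_response": 236,
    "cell_communication": 291,
    "signal_transduction": 245,
    "receptor_activity": 126,
    "apoptosis": 120,
    "cell_cycle": 76,
    "protein_catabolism": 90,
    "protein_folding": 70,
    "oxidative_stress": 39,
}

DEFAULT_CONDITIONS: list[tuple[str, str, int, str]] = [
    ("slow_24h", "slow", 24, "LPS"),
    ("slow_72h", "slow", 72, "LPS"),
    ("fast_24h", "fast", 24, "LPS"),
    ("fast_72h", "fast", 72, "LPS"),
]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment.

    Defaults describe the emulated study: 1818 clones x 6 replicate spots
    on a 12 x 4 meta-grid, four dye-swap pairs of conditions, per-spot
    log2-ratio noise SD 0.3, dye bias amplitude 0.5 log2 units, ~8%
    planted low-quality spots, 5% planted differential genes at
    |log2 FC| = 1.25.
    """

    n_clones: int = 1818
    replicates_per_clone: int = 6
    meta_rows: int = 12
    meta_cols: int = 4
    conditions: list[tuple[str, str, int, str]] = field(
        default_factory=lambda: list(DEFAULT_CONDITIONS))
    baseline_log2_range: tuple[float, float] = (11.0, 21.0)
    spot_sd: float = 0.3
    bg_level: float = 100.0
    bg_sd: float = 10.0
    dye_bias_amplitude: float = 0.5
    row_offset_sd: float = 0.15
    col_offset_sd: float = 0.10
    low_quality_fraction: float = 0.08
    de_fraction: float = 0.05
    de_log2fc: float = 1.25
    enriched_category: str = "immune_response"
    enrichment_bias: float = 0.5
    category_scheme: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SCHEME))
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1 or self.replicates_per_clone < 1:
            raise ParameterError("n_clones and replicates_per_clone must be >= 1")
        for name in ("low_quality_fraction", "de_fraction", "enrichment_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for cat, size in self.category_scheme.items():
            if size > self.n_clones:
                raise ParameterError(
                    f"category {cat!r} size {size} exceeds n_clones "
                    f"{self.n_clones}")
        if self.spot_sd < 0 or self.bg_level <= 0:
            raise ParameterError("spot_sd must be >= 0 and bg_level > 0")


@dataclass
class TruthTable:
    """Planted ground truth of one simulated experiment.

    ``log2_fc``: DataFrame (clone x condition) of true log2 fold changes;
    ``is_de``: same shape, True where a nonzero effect was planted;
    ``low_quality``: rows (SLIDE_ID, CLONE_ID, REP, MECHANISM) of spots
    built to fail the quality filter;
    ``enriched_category``: category over-sampled among planted DEGs.
    """

    log2_fc: pd.DataFrame
    is_de: pd.DataFrame
    low_quality: pd.DataFrame
    enriched_category: str

    def de_genes(self, condition_id: str) -> set[str]:
        flags = self.is_de[condition_id]
        return set(flags.index[flags])

    def null_genes(self, condition_id: str) -> set[str]:
        flags = self.is_de[condition_id]
        return set(flags.index[~flags])

    def low_quality_spots(self, slide_id: str) -> set[tuple[str, int]]:
        sub = self.low_quality[self.low_quality["SLIDE_ID"] == slide_id]
        return set(zip(sub["CLONE_ID"], sub["REP"]))


@dataclass
class SimulatedExperiment:
    slides: list[SlideScan]
    design: ExperimentDesign
    annotation: PlatformAnnotation
    truth: TruthTable
    layout: pd.DataFrame
    baselines: pd.Series


def _clone_ids(n: int) -> list[str]:
    return [f"clone_{i:04d}" for i in range(1, n + 1)]


def generate_platform(config: GeneratorConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[PlatformAnnotation, pd.DataFrame]:
    """Build the platform annotation and the physical spot layout.

    Category membership is sampled independently per category (overlaps
    allowed, as on a real annotation).  The six replicate spots of each
    clone are scattered uniformly over the meta-grid; the true physical
    layout of the emulated platform is not public, so this layout is an
    emulation chosen to exercise the spatial normalization, not a
    reconstruction.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    clones = _clone_ids(config.n_clones)
    annotation_clones: dict[str, tuple[str, str, frozenset[str]]] = {}
    clone_cats: dict[str, set[str]] = {c: set() for c in clones}
    for cat in sorted(config.category_scheme):
        size = config.category_scheme[cat]
        members = rng.choice(config.n_clones, size=size, replace=False)
        for idx in members:
            clone_cats[clones[idx]].add(cat)
    for i, clone in enumerate(clones, start=1):
        annotation_clones[clone] = (f"gene_{i:04d}", f"ACC{i:05d}",
                                    frozenset(clone_cats[clone]))
    categories = {
        cat: (cat.replace("_", " "),
              frozenset(c for c in clones if cat in clone_cats[c]))
        for cat in config.category_scheme
    }
    annotation = PlatformAnnotation(clones=annotation_clones,
                                    categories=categories)

    n_spots = config.n_clones * config.replicates_per_clone
    layout = pd.DataFrame({
        "CLONE_ID": np.repeat(clones, config.replicates_per_clone),
        "REP": np.tile(np.arange(1, config.replicates_per_clone + 1),
                       config.n_clones),
        "BLOCK_ROW": rng.integers(1, config.meta_rows + 1, size=n_spots),
        "BLOCK_COL": rng.integers(1, config.meta_cols + 1, size=n_spots),
    })
    return annotation, layout


def plant_truth(config: GeneratorConfig, annotation: PlatformAnnotation,
                rng: np.random.Generator) -> TruthTable:
    """Plant differential genes per condition.

    ``de_fraction`` of clones get |log2 FC| = ``de_log2fc`` with random
    sign; a fraction ``enrichment_bias`` of them is drawn from the
    enriched category so that the over-representation statistics have a
    planted positive."""
    clones = list(annotation.clones)
    cond_ids = [c[0] for c in config.conditions]
    log2_fc = pd.DataFrame(0.0, index=clones, columns=cond_ids)
    is_de = pd.DataFrame(False, index=clones, columns=cond_ids)
    # sorted: set iteration order is not stable across processes
    enriched = sorted(annotation.categories.get(
        config.enriched_category, ("", frozenset()))[1])
    n_de = int(round(config.de_fraction * len(clones)))
    for cond in cond_ids:
        n_enr = min(int(round(config.enrichment_bias * n_de)), len(enriched))
        chosen = set(rng.choice(enriched, size=n_enr, replace=False)
                     ) if n_enr else set()
        rest_pool = [c for c in clones if c not in chosen]
        n_rest = n_de - len(chosen)
        chosen |= set(rng.choice(rest_pool, size=n_rest, replace=False))
        for clone in sorted(chosen):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            log2_fc.loc[clone, cond] = sign * config.de_log2fc
            is_de.loc[clone, cond] = True
    low_quality = pd.DataFrame(columns=["SLIDE_ID", "CLONE_ID", "REP",
                                        "MECHANISM"])
    return TruthTable(log2_fc=log2_fc, is_de=is_de, low_quality=low_quality,
                      enriched_category=config.enriched_category)


def _draw_background(rng, n, config) -> np.ndarray:
    b = rng.normal(config.bg_level, config.bg_sd, size=n)
    return np.clip(b, 0.6 * config.bg_level, 1.4 * config.bg_level)


def _simulate_slide(slide_id: str, condition_id: str, orientation: str,
                    layout: pd.DataFrame, baselines: pd.Series,
                    truth_fc: pd.Series, config: GeneratorConfig,
                    rng: np.random.Generator
                    ) -> tuple[SlideScan, pd.DataFrame]:
    n = len(layout)
    base = baselines.loc[layout["CLONE_ID"]].to_numpy()
    fc = truth_fc.loc[layout["CLONE_ID"]].to_numpy()
    chan_sd = config.spot_sd / np.sqrt(2.0)
    l_test = base + fc / 2.0 + rng.normal(0.0, chan_sd, size=n)
    l_ctrl = base - fc / 2.0 + rng.normal(0.0, chan_sd, size=n)
    if orientation == "test_ch2":
        l1, l2 = l_ctrl, l_test
    else:
        l1, l2 = l_test, l_ctrl
    # Cy5 (channel 2) carries the dye bias and the spatial block offsets
    row_off = rng.normal(0.0, config.row_offset_sd, size=config.meta_rows)
    col_off = rng.normal(0.0, config.col_offset_sd, size=config.meta_cols)
    bias = (config.dye_bias_amplitude * np.sin(base / 2.0)
            + row_off[layout["BLOCK_ROW"].to_numpy() - 1]
            + col_off[layout["BLOCK_COL"].to_numpy() - 1])
    l2 = l2 + bias

    b1 = _draw_background(rng, n, config)
    b2 = _draw_background(rng, n, config)
    f1 = 2.0 ** l1 + b1
    f2 = 2.0 ** l2 + b2
    s1 = 0.05 * f1
    s2 = 0.05 * f2
    sb1 = 0.1 * b1
    sb2 = 0.1 * b2
    flag = np.zeros(n, dtype=np.int64)

    # Planted low-quality spots, each violating one filter criterion.
    n_bad = int(round(config.low_quality_fraction * n))
    bad_idx = rng.choice(n, size=n_bad, replace=False)
    mechanisms = np.array(["low_ratio", "low_contrast", "flagged"])
    mech = mechanisms[np.arange(n_bad) % len(mechanisms)]
    for idx, how in zip(bad_idx, mech):
        if how == "low_ratio":       # I/B = 2.5 < 3 in channel 1
            f1[idx] = 2.5 * b1[idx]
            s1[idx] = 0.05 * f1[idx]
        elif how == "low_contrast":  # (I-B)/(SI+SB) = 0.3 < 0.6 in channel 2
            s2[idx] = (f2[idx] - b2[idx]) / 0.3 - sb2[idx]
        else:
            flag[idx] = 1
    planted = pd.DataFrame({
        "SLIDE_ID": slide_id,
        "CLONE_ID": layout["CLONE_ID"].to_numpy()[bad_idx],
        "REP": layout["REP"].to_numpy()[bad_idx],
        "MECHANISM": mech,
    })

    genes = [f"gene_{int(c.split('_')[1]):04d}"
             for c in layout["CLONE_ID"]]
    spots = pd.DataFrame({
        "CLONE_ID": layout["CLONE_ID"].to_numpy(),
        "GENE": genes,
        "BLOCK_ROW": layout["BLOCK_ROW"].to_numpy(),
        "BLOCK_COL": layout["BLOCK_COL"].to_numpy(),
        "REP": layout["REP"].to_numpy(),
        "F1_MED": f1, "B1_MED": b1, "F1_SD": s1, "B1_SD": sb1,
        "F2_MED": f2, "B2_MED": b2, "F2_SD": s2, "B2_SD": sb2,
        "FLAG": flag,
    }, columns=SPOT_COLUMNS)
    slide = SlideScan(slide_id=slide_id, condition_id=condition_id,
                      dye_orientation=orientation, spots=spots,
                      meta_grid=(config.meta_rows, config.meta_cols))
    return slide, planted


def simulate_experiment(config: GeneratorConfig | None = None,
                        truth: TruthTable | None = None,
                        seed: int | None = None) -> SimulatedExperiment:
    """Generate the full slide set with ground truth.

    A caller-supplied ``truth`` table (e.g. with hand-planted
    tissue-specific effects) overrides the default random planting; it
    must index all clones and all configured conditions.  Everything is
    reproducible from (config, seed).
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    annotation, layout = generate_platform(config, rng)
    if truth is None:
        truth = plant_truth(config, annotation, rng)
    lo, hi = config.baseline_log2_range
    baselines = pd.Series(rng.uniform(lo, hi, size=config.n_clones),
                          index=list(annotation.clones))

    design = ExperimentDesign()
    slides: list[SlideScan] = []
    planted_frames = []
    slide_no = 0
    for cond_id, tissue, timepoint, treatment in config.conditions:
        pair_ids = []
        for orientation in ("test_ch2", "test_ch1"):
            slide_no += 1
            slide_id = f"S{slide_no:02d}"
            slide, planted = _simulate_slide(
                slide_id, cond_id, orientation, layout, baselines,
                truth.log2_fc[cond_id], config, rng)
            slides.append(slide)
            planted_frames.append(planted)
            pair_ids.append(slide_id)
        design.conditions.append((cond_id, tissue, timepoint, treatment))
        design.pairs[cond_id] = (pair_ids[0], pair_ids[1])

    truth = TruthTable(log2_fc=truth.log2_fc, is_de=truth.is_de,
                       low_quality=pd.concat(planted_frames,
                                             ignore_index=True),
                       enriched_category=truth.enriched_category)
    return SimulatedExperiment(slides=slides, design=design,
                               annotation=annotation, truth=truth,
                               layout=layout, baselines=baselines)


def null_truth(config: GeneratorConfig) -> TruthTable:
    """An all-null truth table (no planted effects) for calibration runs."""
    clones = _clone_ids(config.n_clones)
    cond_ids = [c[0] for c in config.conditions]
    return TruthTable(
        log2_fc=pd.DataFrame(0.0, index=clones, columns=cond_ids),
        is_de=pd.DataFrame(False, index=clones, columns=cond_ids),
        low_quality=pd.DataFrame(columns=["SLIDE_ID", "CLONE_ID", "REP",
                                          "MECHANISM"]),
        enriched_category=config.enriched_category)


# ---------------------------------------------------------------------------
# quality-filter fixture

def make_quality_fixture(n_spots: int, fail_fraction: float, seed: int,
                         meta_grid: tuple[int, int] = (12, 4)
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Construct a spot table with planted pass/fail status.

    Passing spots satisfy both quality criteria in both channels with wide
    margins; failing spots are built to violate exactly one criterion
    (signal-to-background, contrast, scanner flag, or a non-positive net
    signal).  Returns the table and the planted boolean pass mask.
    """
    rng = np.random.default_rng(seed)
    n_fail = int(round(fail_fraction * n_spots))
    passed = np.ones(n_spots, dtype=bool)
    passed[rng.choice(n_spots, size=n_fail, replace=False)] = False

    b1 = rng.uniform(80.0, 120.0, n_spots)
    b2 = rng.uniform(80.0, 120.0, n_spots)
    f1 = b1 * rng.uniform(4.0, 20.0, n_spots)
    f2 = b2 * rng.uniform(4.0, 20.0, n_spots)
    s1, s2 = 0.05 * f1, 0.05 * f2
    sb1, sb2 = 0.1 * b1, 0.1 * b2
    flag = np.zeros(n_spots, dtype=np.int64)

    mechanisms = ["low_ratio", "low_contrast", "flagged", "negative_net"]
    fail_idx = np.flatnonzero(~passed)
    for j, idx in enumerate(fail_idx):
        how = mechanisms[j % len(mechanisms)]
        if how == "low_ratio":
            f1[idx] = b1[idx] * rng.uniform(1.2, 2.5)
        elif how == "low_contrast":
            s2[idx] = (f2[idx] - b2[idx]) / rng.uniform(0.2, 0.5) - sb2[idx]
        elif how == "flagged":
            flag[idx] = 1
        else:
            f2[idx] = b2[idx] * rng.uniform(0.3, 0.9)
    spots = pd.DataFrame({
        "CLONE_ID": [f"fx_{i:05d}" for i in range(n_spots)],
        "GENE": [f"fxg_{i:05d}" for i in range(n_spots)],
        "BLOCK_ROW": rng.integers(1, meta_grid[0] + 1, n_spots),
        "BLOCK_COL": rng.integers(1, meta_grid[1] + 1, n_spots),
        "REP": np.ones(n_spots, dtype=np.int64),
        "F1_MED": f1, "B1_MED": b1, "F1_SD": s1, "B1_SD": sb1,
        "F2_MED": f2, "B2_MED": b2, "F2_SD": s2, "B2_SD": sb2,
        "FLAG": flag,
    }, columns=SPOT_COLUMNS)
    return spots, passed


# ---------------------------------------------------------------------------
# qPCR simulation

@dataclass
class QpcrSim:
    """Simulated qPCR assay: per-gene dilution series, well-level Ct table,
    and the generating curve parameters."""

    dilution_series: dict[str, pd.DataFrame]
    ct_table: pd.DataFrame
    true_slopes: dict[str, float]
    true_intercepts: dict[str, float]


def simulate_qpcr(config: GeneratorConfig, truth: TruthTable,
                  condition_id: str, genes: list[str] | None = None,
                  seed: int | None = None, n_samples: int = 3,
                  reference_gene: str = "18S",
                  ct_noise_sd: float = 0.05,
                  bio_log2_sd: float = 0.1) -> QpcrSim:
    """Simulate standard curves and a triplicate Ct table for one condition.

    Per-gene curves have slope -3.3219 (perfect doubling) with small
    jitter; target genes start from ~1e4 copies in the control group and
    shift by the planted log2 FC in the treated group; the reference gene
    sits at ~1e7 copies in both groups, stable well within the 7% Ct gate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if genes is None:
        de = sorted(truth.de_genes(condition_id))
        genes = de[:6] if de else sorted(truth.log2_fc.index[:6])
    all_genes = list(genes) + [reference_gene]

    slopes, intercepts, dilutions = {}, {}, {}
    for gene in all_genes:
        slope = -3.3219 + rng.normal(0.0, 0.01)
        intercept = rng.uniform(34.0, 38.0)
        x = np.arange(1.0, 7.0)          # 10^1 .. 10^6 copies
        ct = slope * x + intercept + rng.normal(0.0, ct_noise_sd, len(x))
        slopes[gene] = slope
        intercepts[gene] = intercept
        dilutions[gene] = pd.DataFrame({"LOG10_COPIES": x, "CT": ct})

    rows = []
    for group in ("control", "treated"):
        for s in range(1, n_samples + 1):
            sample_id = f"{condition_id}_{group}_{s}"
            for gene in all_genes:
                if gene == reference_gene:
                    copies = 1e7 * 2.0 ** rng.normal(0.0, 0.02)
                else:
                    base = 1e4 * 2.0 ** rng.normal(0.0, bio_log2_sd)
                    fc = float(truth.log2_fc.loc[gene, condition_id]) \
                        if group == "treated" else 0.0
                    copies = base * 2.0 ** fc
                true_ct = slopes[gene] * np.log10(copies) + intercepts[gene]
                for rep in range(1, 4):
                    rows.append({"SAMPLE_ID": sample_id, "GROUP": group,
                                 "GENE": gene, "REP": rep,
                                 "CT": true_ct + rng.normal(0.0, ct_noise_sd)})
    ct_table = pd.DataFrame(rows, columns=["SAMPLE_ID", "GROUP", "GENE",
                                           "REP", "CT"])
    return QpcrSim(dilution_series=dilutions, ct_table=ct_table,
                   true_slopes=slopes, true_intercepts=intercepts)
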
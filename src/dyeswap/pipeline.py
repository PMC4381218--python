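"""End-to-end orchestration: generate -> preprocess -> DGE -> GO -> qPCR.

``run_pipeline`` executes the whole analysis on a synthetic experiment (or
on slide files read from disk), writes every result as TSV plus a
machine-readable JSON run manifest, and is byte-deterministic: identical
config and seed produce identical output files.  Per-stage counts (spots
read, spots filtered, genes discarded, DEGs called) are accumulated in the
report so the headline numbers of a run can be re-derived from its logs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .array_io import ExperimentDesign, PlatformAnnotation, SlideScan
from .dge import (DEGTable, VennPartition, call_degs, combine_dye_swap,
                  compare_conditions, gene_statistics)
from .errors import DyeswapError
from .go_enrich import enrichment_report
from .preprocess import RatioSet, preprocess_slide, write_ratio_set
from .qpcr import (fit_standard_curve, relative_expression,
                   validate_against_microarray)
from .simulate import (GeneratorConfig, SimulatedExperiment, simulate_qpcr,
                       simulate_experiment)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run."""

    outdir: str = "dyeswap_run"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # quality filter
    t_ratio: float = 3.0
    t_contrast: float = 0.6
    min_spots: int = 3
    # normalization
    span: float = 0.3
    robust_iters: int = 3
    min_group: int = 20
    norm_mode: str = "marginal"
    # differential expression
    p_threshold: float = 0.01
    fc_threshold: float = 1.5
    # category statistics
    go_alpha: float = 0.05
    bh_adjust: bool = False
    # extras
    run_qpcr: bool = True
    write_ratio_diagnostics: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["conditions"] = [list(c) for c in
                                        d["generator"]["conditions"]]
        # the output location is where the manifest lives, not part of the
        # analysis identity; keeping it out makes re-runs byte-comparable
        d.pop("outdir")
        return d


@dataclass
class RunReport:
    """Everything a run produced, in memory plus on disk."""

    config: RunConfig
    outdir: Path
    stage_counts: dict = field(default_factory=dict)
    deg_tables: dict[str, DEGTable] = field(default_factory=dict)
    venns: dict[str, VennPartition] = field(default_factory=dict)
    go_reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    qpcr_validation: dict[str, pd.DataFrame] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, DyeswapError):
                exc.args = (f"[stage {name}] {exc.args[0]}",
                            *exc.args[1:])
            return False
    return _Ctx()


def _write_tsv(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")
    report.files.append(str(path))


def run_pipeline(config: RunConfig | None = None,
                 experiment: SimulatedExperiment | None = None,
                 slides: list[SlideScan] | None = None,
                 design: ExperimentDesign | None = None,
                 annotation: PlatformAnnotation | None = None) -> RunReport:
    """Run the full analysis and write all result tables under
    ``config.outdir``.

    With no explicit inputs, a synthetic experiment is generated from
    ``config.generator`` and ``config.seed``.  Alternatively pass a
    pre-built :class:`SimulatedExperiment`, or raw ``slides`` + ``design``
    + ``annotation`` read from disk.
    """
    config = config or RunConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config, outdir=outdir)

    with _stage("generate"):
        if slides is None:
            if experiment is None:
                gen = dataclasses.replace(config.generator, seed=config.seed)
                experiment = simulate_experiment(gen, seed=config.seed)
            slides = experiment.slides
            design = experiment.design
            annotation = experiment.annotation
        if design is None or annotation is None:
            raise DyeswapError("explicit slides need design and annotation")
    report.stage_counts["n_slides"] = len(slides)
    report.stage_counts["n_clones"] = annotation.n_clones

    with _stage("preprocess"):
        ratio_sets: dict[str, RatioSet] = {}
        spots_read = spots_failed = genes_discarded = 0
        for slide in slides:
            ratios, filt = preprocess_slide(
                slide, t_ratio=config.t_ratio, t_contrast=config.t_contrast,
                min_spots=config.min_spots, span=config.span,
                robust_iters=config.robust_iters, min_group=config.min_group,
                mode=config.norm_mode)
            ratio_sets[slide.slide_id] = ratios
            spots_read += filt.n_spots_in
            spots_failed += filt.n_spots_failed
            genes_discarded += len(filt.removed_genes)
            if config.write_ratio_diagnostics:
                path = outdir / f"ratios_{slide.slide_id}.tsv"
                write_ratio_set(ratios, path)
                report.files.append(str(path))
    report.stage_counts["spots_read"] = spots_read
    report.stage_counts["spots_failed_filter"] = spots_failed
    report.stage_counts["gene_slide_discards"] = genes_discarded

    with _stage("dge"):
        for cond_id in design.condition_ids():
            s1, s2 = design.pairs[cond_id]
            matrix = combine_dye_swap(ratio_sets[s1], ratio_sets[s2],
                                      min_spots_per_slide=config.min_spots)
            stats = gene_statistics(matrix).sort_values("gene")
            table = call_degs(stats, cond_id,
                              p_threshold=config.p_threshold,
                              fc_threshold=config.fc_threshold)
            report.deg_tables[cond_id] = table
            _write_tsv(table.stats, outdir / f"dge_{cond_id}.tsv", report)
            total, up, down = table.counts
            report.stage_counts[f"degs_{cond_id}"] = {
                "total": total, "up": up, "down": down,
                "analyzable": len(stats)}

    with _stage("compare"):
        by_key: dict[tuple[str, int], list[str]] = {}
        cond_meta = {c[0]: (c[1], c[2]) for c in design.conditions}
        for cond_id, (tissue, timepoint) in cond_meta.items():
            by_key.setdefault((timepoint,), []).append(cond_id)
        venn_rows = []
        for (timepoint,), conds in sorted(by_key.items()):
            if len(conds) != 2:
                continue
            a, b = sorted(conds)
            venn = compare_conditions(report.deg_tables[a],
                                      report.deg_tables[b])
            key = f"{a}_vs_{b}"
            report.venns[key] = venn
            na, nb, nc = venn.counts
            venn_rows.append({"comparison": key, "only_a": na, "only_b": nb,
                              "common": nc, "excluded": len(venn.excluded)})
        if venn_rows:
            _write_tsv(pd.DataFrame(venn_rows), outdir / "venn_summary.tsv",
                       report)

    with _stage("go"):
        for cond_id, table in report.deg_tables.items():
            rep = enrichment_report(table, annotation.categories,
                                    alpha=config.go_alpha,
                                    bh_adjust=config.bh_adjust)
            report.go_reports[cond_id] = rep
            _write_tsv(rep, outdir / f"go_{cond_id}.tsv", report)

    if config.run_qpcr and experiment is not None:
        with _stage("qpcr"):
            for cond_id, table in report.deg_tables.items():
                sim = simulate_qpcr(config.generator, experiment.truth,
                                    cond_id, seed=config.seed)
                curves = {g: fit_standard_curve(d["LOG10_COPIES"], d["CT"], g)
                          for g, d in sim.dilution_series.items()}
                fc = relative_expression(sim.ct_table, curves)
                ma_fc = dict(zip(table.stats["gene"], table.stats["fc"]))
                qpcr_fc = {g: r.fold_change for g, r in fc.items()
                           if g in ma_fc}
                if not qpcr_fc:
                    continue
                agreement = validate_against_microarray(qpcr_fc, ma_fc)
                report.qpcr_validation[cond_id] = agreement
                _write_tsv(agreement, outdir / f"qpcr_validation_{cond_id}.tsv",
                           report)

    with _stage("manifest"):
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stage_counts": report.stage_counts,
        }
        path = outdir / "run_manifest.json"
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report.files.append(str(path))
    return report
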
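"""qPCR standard-curve quantification, 18S normalization and fold changes.

Quantification is absolute: a standard curve Ct = slope * log10(copies) +
intercept is fitted by least squares to a plasmid dilution series, each
sample's triplicate-mean Ct is converted to a copy number through the
curve, target copies are normalized to the 18S ribosomal RNA reference,
and the fold change of the treated group is the ratio of group means of
the normalized values, mapped to the sign-magnitude convention (a ratio
of 0.25 reads -4.0).  An efficiency-corrected ddCt alternative is
available behind ``method="ddct"``.

Curve quality gates follow common practice for SYBR assays: r^2 > 0.99
and amplification efficiency 10**(-1/slope) - 1 > 0.99.  Reference
stability is checked as the percent difference of group-mean reference
Cts against a 7% gate; violation warns rather than fails, since the
check is diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError, ParameterError

CT_COLUMNS = ["SAMPLE_ID", "GROUP", "GENE", "REP", "CT"]
GROUPS = ("control", "treated")


@dataclass
class StandardCurve:
    gene: str
    slope: float          # Ct per log10 copies; < 0 for a working assay
    intercept: float      # Ct at 1 copy
    r_squared: float
    efficiency: float     # 10**(-1/slope) - 1; 1.0 = perfect doubling

    def passes_quality(self, min_r2: float = 0.99,
                       min_efficiency: float = 0.99) -> bool:
        return self.r_squared > min_r2 and self.efficiency > min_efficiency


@dataclass
class FoldChangeResult:
    gene: str
    fold_change: float            # sign-magnitude vs control
    ratio: float                  # raw treated/control ratio of means
    n_control: int
    n_treated: int
    reference_stability_pct: float
    reference_stable: bool        # within the 7% gate


def sign_magnitude(ratio: float) -> float:
    """Map a linear expression ratio to the sign-magnitude convention:
    ratios >= 1 unchanged, ratios < 1 become the negative reciprocal."""
    if ratio <= 0 or not math.isfinite(ratio):
        raise ParameterError(f"expression ratio must be finite and > 0, "
                             f"got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio

def ratio_from_sign_magnitude(fc: float) -> float:
    """Inverse of :func:`sign_magnitude`."""
    if abs(fc) < 1.0:
        raise ParameterError(f"sign-magnitude fold change has |fc| >= 1, "
                             f"got {fc}")
    return fc if fc >= 1.0 else -1.0 / fc


def fit_standard_curve(log10_copies, ct, gene: str = "") -> StandardCurve:
    """Least-squares standard curve from a dilution series.

    Requires at least 3 points spanning at least 2 decades of copy number;
    a non-negative slope means Ct did not fall with template amount and the
    curve is rejected.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) < 3:
        raise ParameterError("standard curve needs at least 3 dilution points")
    if x.max() - x.min() < 2.0:
        raise ParameterError("dilution series must span at least 2 log10 "
                             "of copy number")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise IntegrityError(
            f"standard curve for {gene or 'gene'} has non-negative slope "
            f"{res.slope:.3f}; amplification did not track template amount")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(gene=gene, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue) ** 2,
                         efficiency=float(efficiency))


def quantify(ct: float, curve: StandardCurve) -> float:
    """Copy number for a Ct through the standard curve:
    copies = 10**((ct - intercept) / slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table TSV (SAMPLE_ID, GROUP, GENE, REP, CT)."""
    df = pd.read_csv(path, sep="\t", dtype={"SAMPLE_ID": str, "GROUP": str,
                                            "GENE": str}, comment="#")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing Ct table column(s) {missing}")
    return df[CT_COLUMNS]


def validate_ct_table(ct_table: pd.DataFrame) -> None:
    ct = ct_table["CT"].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise IntegrityError("Ct values must be finite and > 0")
    bad = set(ct_table["GROUP"]) - set(GROUPS)
    if bad:
        raise IntegrityError(f"unknown group label(s) {sorted(bad)}")


def _mean_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Triplicate-mean Ct per (sample, group, gene)."""
    return (ct_table.groupby(["SAMPLE_ID", "GROUP", "GENE"], sort=False)
            ["CT"].mean().reset_index())


def relative_expression(ct_table: pd.DataFrame,
                        curves: dict[str, StandardCurve],
                        reference_gene: str = "18S",
                        stability_gate_pct: float = 7.0,
                        method: str = "standard_curve"
                        ) -> dict[str, FoldChangeResult]:
    """Fold change of each target gene vs the control group.

    Per sample, the triplicate-mean Ct of the target is converted to
    copies, divided by the reference copies of the same sample, and the
    fold change is mean(treated) / mean(control) of those normalized
    values mapped to sign-magnitude.  With ``method="ddct"``, copies are
    replaced by (1 + E)**(-Ct) with the curve's efficiency E, an
    efficiency-corrected ddCt that cancels the intercept.
    """
    if method not in ("standard_curve", "ddct"):
        raise ParameterError(f"unknown quantification method {method!r}")
    validate_ct_table(ct_table)
    means = _mean_ct(ct_table)
    genes = [g for g in means["GENE"].unique() if g != reference_gene]
    ref = means[means["GENE"] == reference_gene].set_index("SAMPLE_ID")
    if len(ref) == 0:
        raise IntegrityError(f"reference gene {reference_gene!r} missing "
                             "from the Ct table")

    def copies(gene: str, ct: np.ndarray) -> np.ndarray:
        curve = curves.get(gene)
        if curve is None:
            raise IntegrityError(f"no standard curve for gene {gene!r}")
        if method == "standard_curve":
            return np.array([quantify(c, curve) for c in ct])
        return (1.0 + curve.efficiency) ** (-ct)

    # reference stability: percent difference of group-mean reference Ct
    ref_group = ref.groupby("GROUP")["CT"].mean()
    if set(ref_group.index) != set(GROUPS):
        raise IntegrityError("reference gene must be measured in both groups")
    stability = abs(ref_group["treated"] - ref_group["control"]) \
        / ref_group["control"] * 100.0
    stable = stability < stability_gate_pct
    if not stable:
        warnings.warn(
            f"reference gene {reference_gene!r} group-mean Ct differs by "
            f"{stability:.1f}% (gate {stability_gate_pct}%)", stacklevel=2)

    ref_copies = pd.Series(copies(reference_gene,
                                  ref["CT"].to_numpy(dtype=float)),
                           index=ref.index)
    results: dict[str, FoldChangeResult] = {}
    for gene in genes:
        sub = means[means["GENE"] == gene]
        missing_ref = set(sub["SAMPLE_ID"]) - set(ref_copies.index)
        if missing_ref:
            raise IntegrityError(f"gene {gene!r}: sample(s) without a "
                                 f"reference measurement: {sorted(missing_ref)}")
        target = copies(gene, sub["CT"].to_numpy(dtype=float))
        norm = target / ref_copies.loc[sub["SAMPLE_ID"]].to_numpy()
        groups = sub["GROUP"].to_numpy()
        ctrl = norm[groups == "control"]
        trt = norm[groups == "treated"]
        if len(ctrl) == 0 or len(trt) == 0:
            raise IntegrityError(f"gene {gene!r}: both groups must be measured")
        ratio = float(np.mean(trt) / np.mean(ctrl))
        results[gene] = FoldChangeResult(
            gene=gene, fold_change=sign_magnitude(ratio), ratio=ratio,
            n_control=len(ctrl), n_treated=len(trt),
            reference_stability_pct=float(stability),
            reference_stable=bool(stable))
    return results


def validate_against_microarray(qpcr_fc: dict[str, float],
                                ma_fc: dict[str, float]) -> pd.DataFrame:
    """Gene-by-gene agreement between qPCR and microarray fold changes.

    Both inputs are sign-magnitude fold changes.  The magnitude ratio is
    computed on the linear ratio scale (qPCR over microarray), and the
    summary row fraction of direction-concordant genes is exposed via
    ``df.attrs['direction_concordance']``.
    """
    genes = sorted(set(qpcr_fc) & set(ma_fc))
    if not genes:
        raise ParameterError("qPCR and microarray gene lists do not overlap")
    rows = []
    for gene in genes:
        q, m = qpcr_fc[gene], ma_fc[gene]
        same = (q >= 1 and m >= 1) or (q <= -1 and m <= -1)
        ratio = ratio_from_sign_magnitude(q) / ratio_from_sign_magnitude(m)
        rows.append({"gene": gene, "qpcr_fc": q, "ma_fc": m,
                     "same_direction": same, "magnitude_ratio": ratio})
    df = pd.DataFrame(rows)
    df.attrs["direction_concordance"] = float(df["same_direction"].mean())
    return df
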
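"""Standard-curve efficiency and Pfaffl relative expression for qRT-PCR.

Amplification efficiency E (in percent) comes from the slope ``a`` of the
standard curve of Ct against log10 template amount:

    E = (10^(1/|a|) - 1) * 100

so a = -3.3219 (perfect doubling) gives E = 100%.  The magnitude of the
slope is used so that either sign convention for ``a`` yields the expected
positive efficiency.

Relative expression against a calibrator sample follows the Pfaffl method,
which corrects each gene for its own amplification efficiency:

    Er = (1 + E_target/100)^dCt_target / (1 + E_ref/100)^dCt_ref

with dCt = Ct(calibrator) - Ct(sample), so that higher expression than the
calibrator gives Er > 1 and the calibrator itself has Er = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StandardCurve:
    """Fitted standard curve: slope of Ct vs log10 input (conventionally negative)."""

    slope_a: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope_a == 0:
            raise ValueError("standard-curve slope must be nonzero")


def efficiency_from_slope(curve: StandardCurve | float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    Accepts either a :class:`StandardCurve` or a bare slope.  Strictly
    decreasing in |a|; |a| -> infinity gives E -> 0.
    """
    a = curve.slope_a if isinstance(curve, StandardCurve) else float(curve)
    if a == 0:
        raise ValueError("standard-curve slope must be nonzero")
    return (10.0 ** (1.0 / abs(a)) - 1.0) * 100.0


def pfaffl_ratio(E_target_pct: float, E_ref_pct: float,
                 dCt_target: float, dCt_ref: float) -> float:
    """Efficiency-corrected relative expression ratio (Pfaffl).

    dCt values are Ct(calibrator) - Ct(sample), in cycles.  With both
    efficiencies at 100% this reduces exactly to 2^(dCt_target - dCt_ref).
    """
    if E_target_pct <= -100 or E_ref_pct <= -100:
        raise ValueError("efficiencies must exceed -100%")
    b_t = 1.0 + E_target_pct / 100.0
    b_r = 1.0 + E_ref_pct / 100.0
    return (b_t ** dCt_target) / (b_r ** dCt_ref)


REQUIRED_CT_COLUMNS = ("gene", "condition", "timepoint_h", "replicate", "Ct")


class CtDataError(ValueError):
    """Missing or malformed cells in a Ct table."""


def relative_expression_table(
    ct_table: pd.DataFrame,
    target_genes: list[str],
    reference_gene: str,
    calibrator: tuple[str, float],
    efficiencies_pct: Mapping[str, float] | None = None,
    paired_calibrator: bool = False,
) -> pd.DataFrame:
    """Per-gene Pfaffl relative expression, mean +- SEM over replicates.

    ct_table is long format with columns gene, condition, timepoint_h,
    replicate, Ct.  ``calibrator`` is the (condition, timepoint_h) pair whose
    expression is defined as 1 (typically the 0-h untreated control...
    represented at the earliest measured timepoint).  Efficiencies default to
    100% per gene.

    By default each replicate's dCt is taken against the replicate-mean
    calibrator Ct; ``paired_calibrator=True`` instead pairs replicate r of a
    sample with replicate r of the calibrator.

    Returns rows (gene, condition, timepoint_h, n_replicates, Er_mean,
    Er_sem); SEM is NaN for a single replicate, never 0.
    """
    missing_cols = [c for c in REQUIRED_CT_COLUMNS if c not in ct_table.columns]
    if missing_cols:
        raise CtDataError(f"Ct table missing columns {missing_cols}")
    eff = dict(efficiencies_pct or {})
    cal_cond, cal_tp = calibrator

    def cell(gene: str, cond: str, tp: float) -> pd.DataFrame:
        sel = ct_table[
            (ct_table["gene"] == gene)
            & (ct_table["condition"] == cond)
            & (ct_table["timepoint_h"] == tp)
        ]
        return sel.sort_values("replicate")

    # calibrator Cts must exist for the reference and every target
    for gene in [reference_gene, *target_genes]:
        if cell(gene, cal_cond, cal_tp).empty:
            raise CtDataError(
                f"missing calibrator Ct for gene={gene!r}, "
                f"condition={cal_cond!r}, timepoint={cal_tp}"
            )

    conditions = ct_table[["condition", "timepoint_h"]].drop_duplicates()
    out_rows = []
    for gene in target_genes:
        E_t = eff.get(gene, 100.0)
        E_r = eff.get(reference_gene, 100.0)
        cal_t = cell(gene, cal_cond, cal_tp)["Ct"].to_numpy()
        cal_r_all = cell(reference_gene, cal_cond, cal_tp)["Ct"].to_numpy()
        for _, (cond, tp) in conditions.iterrows():
            samp_t = cell(gene, cond, tp)
            samp_r = cell(reference_gene, cond, tp)
            if samp_t.empty:
                continue
            if samp_r.empty:
                raise CtDataError(
                    f"missing reference-gene Ct for condition={cond!r}, timepoint={tp}"
                )
            ct_t = samp_t["Ct"].to_numpy()
            ct_r = samp_r["Ct"].to_numpy()
            if len(ct_r) != len(ct_t):
                raise CtDataError(
                    f"replicate mismatch between {gene!r} and reference at "
                    f"({cond!r}, {tp}): {len(ct_t)} vs {len(ct_r)}"
                )
            ers = []
            for i in range(len(ct_t)):
                if paired_calibrator:
                    if i >= len(cal_t) or i >= len(cal_r_all):
                        raise CtDataError(
                            f"paired calibrator replicate {i} missing for {gene!r}"
                        )
                    dct_t = cal_t[i] - ct_t[i]
                    dct_r = cal_r_all[i] - ct_r[i]
                else:
                    dct_t = cal_t.mean() - ct_t[i]
                    dct_r = cal_r_all.mean() - ct_r[i]
                ers.append(pfaffl_ratio(E_t, E_r, dct_t, dct_r))
            ers = np.asarray(ers)
            sem = float(ers.std(ddof=1) / np.sqrt(len(ers))) if len(ers) > 1 else float("nan")
            out_rows.append(
                (gene, cond, tp, len(ers), float(ers.mean()), sem)
            )
    return pd.DataFrame(
        out_rows,
        columns=["gene", "condition", "timepoint_h", "n_replicates", "Er_mean", "Er_sem"],
    )
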
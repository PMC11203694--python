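"""Within-batch differential MSox peptidoform analysis (5XFAD vs WT).

Fold changes are ratios of group mean AUC (5XFAD/WT). Significance uses
the unpaired two-sample t-test, by default on log2-transformed AUC with
pooled (Student) variance. Volcano classification applies joint
fold-change and p-value thresholds (fold change ≥ 2 or ≤ 0.5 and
p ≤ 0.1); the enrichment input set uses the stricter log2FC ≥ 4 cut.

Quantitative comparisons are only meaningful within one acquisition
batch; :func:`check_same_batch` guards against cross-batch requests.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .ingest import StudyDesign

logger = logging.getLogger(__name__)

UP = "UP"
DOWN = "DOWN"
NS = "NS"
NA = "NA"


class CrossBatchError(ValueError):
    """Raised when a quantitative comparison spans acquisition batches."""


def check_same_batch(design: StudyDesign, samples_a: Sequence[str], samples_b: Sequence[str]) -> None:
    batches = design.batches_of(samples_a) | design.batches_of(samples_b)
    if len(batches) > 1:
        raise CrossBatchError(
            f"quantitative comparison across batches {sorted(batches)} is invalid: "
            "batches are not absolutely standardized against each other"
        )


def _finite(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[np.isfinite(a)]


def fold_change(wt_values, fad_values) -> float:
    """Ratio of group mean AUC, 5XFAD / WT; NaN when a group is all-missing."""
    wt, fad = _finite(wt_values), _finite(fad_values)
    if wt.size == 0 or fad.size == 0:
        return float("nan")
    return float(fad.mean() / wt.mean())


def unpaired_t(
    wt_values,
    fad_values,
    on_log2: bool = True,
    equal_var: bool = True,
    min_n: int = 3,
) -> float:
    """Two-sided unpaired t-test p-value between two AUC vectors.

    By default the test is run on log2(AUC) — a variance-stabilising
    transform for multiplicative intensity noise — with pooled (Student)
    variance; ``equal_var=False`` gives Welch. Returns NaN below ``min_n``
    finite values per group; returns 1.0 for two identical constant
    groups (zero pooled variance, zero difference).
    """
    wt, fad = _finite(wt_values), _finite(fad_values)
    if wt.size < min_n or fad.size < min_n:
        return float("nan")
    if on_log2:
        if (wt <= 0).any() or (fad <= 0).any():
            raise ValueError("log2 scale requires strictly positive AUC values")
        wt, fad = np.log2(wt), np.log2(fad)
    if np.ptp(wt) == 0 and np.ptp(fad) == 0:
        return 1.0 if wt[0] == fad[0] else 0.0
    res = stats.ttest_ind(fad, wt, equal_var=equal_var)
    return float(res.pvalue)


def volcano_classify(
    fc: float,
    p: float,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    p_max: float = 0.1,
) -> str:
    """Label one peptidoform UP/DOWN/NS from its fold change and p-value."""
    if fc_down >= fc_up:
        raise ValueError(f"fc_down ({fc_down}) must be < fc_up ({fc_up})")
    if not np.isfinite(fc) or not np.isfinite(p):
        return NA
    if p <= p_max and fc >= fc_up:
        return UP
    if p <= p_max and fc <= fc_down:
        return DOWN
    return NS


def differential_table(
    table: pd.DataFrame,
    design: StudyDesign,
    timepoint: str,
    wt_label: str = "WT",
    fad_label: str = "FAD5X",
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    p_max: float = 0.1,
    on_log2: bool = True,
    equal_var: bool = True,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-peptidoform differential results for one time-point batch.

    Returns a frame with fc, log2fc, raw p, BH q (reported for
    transparency; calls use raw p), per-group detection counts and the
    volcano call.
    """
    wt_samples = design.samples(timepoint=timepoint, genotype=wt_label)
    fad_samples = design.samples(timepoint=timepoint, genotype=fad_label)
    if not wt_samples or not fad_samples:
        raise ValueError(f"no samples for timepoint {timepoint!r}")
    check_same_batch(design, wt_samples, fad_samples)

    wt_mat = table[wt_samples].to_numpy(dtype=float)
    fad_mat = table[fad_samples].to_numpy(dtype=float)

    rows = []
    for i in range(len(table)):
        wt, fad = wt_mat[i], fad_mat[i]
        fc = fold_change(wt, fad)
        p = unpaired_t(wt, fad, on_log2=on_log2, equal_var=equal_var, min_n=min_n)
        rows.append(
            {
                "peptidoform": table["peptidoform"].iloc[i],
                "protein": table["protein"].iloc[i],
                "fc": fc,
                "log2fc": float(np.log2(fc)) if np.isfinite(fc) and fc > 0 else float("nan"),
                "p": p,
                "n_wt": int(np.isfinite(wt).sum()),
                "n_fad": int(np.isfinite(fad).sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    defined = out["p"].notna()
    if defined.any():
        out.loc[defined, "q"] = bh_fdr(out.loc[defined, "p"].to_numpy())
    out["call"] = [
        volcano_classify(fc, p, fc_up, fc_down, p_max) if np.isfinite(p) else NA
        for fc, p in zip(out["fc"], out["p"])
    ]
    logger.info(
        "differential %s: %d peptidoforms, %d UP, %d DOWN",
        timepoint, len(out), (out["call"] == UP).sum(), (out["call"] == DOWN).sum(),
    )
    return out


def select_enrichment_input(
    results: pd.DataFrame,
    log2fc_min: float = 4.0,
    p_max: float = 0.1,
) -> pd.DataFrame:
    """Highly upregulated peptidoforms (log2FC ≥ 4, p ≤ 0.1) for enrichment."""
    if results.empty:
        return results
    keep = (results["log2fc"] >= log2fc_min) & (results["p"] <= p_max)
    return results[keep.fillna(False)].reset_index(drop=True)
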
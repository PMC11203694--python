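"""Oxidation occupancy (stoichiometry) from paired peptidoform AUC pools.

For a protein and a pool of peptide sequences, each sample's oxidized
AUC sum (peptidoforms with ≥1 MSox site) and unoxidized AUC sum (same
bare sequences, no MSox) give the occupancy

    occupancy % = 100 × ox / (ox + unox),

the fraction of the peptide pool present in the sulfoxide form.
Occupancy is computed per sample (per mouse) and then summarised across
a group, which preserves biological replication and supports Cohen's d
effect sizes between genotypes. A sample with no detected oxidized form
but a detected unoxidized form is at (or below) the lower limit of
detection: it is scored 0% and flagged censored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import msox_sites, sample_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d between two groups of occupancy percentages."""

    d: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    pooled_sd: float


def occupancy_percent(ox_auc, unox_auc):
    """Percent of a pool in the oxidized form: 100 × ox/(ox + unox).

    Accepts scalars or arrays; returns NaN where ox + unox == 0 (neither
    species detected — occupancy undefined).
    """
    ox = np.asarray(ox_auc, dtype=float)
    unox = np.asarray(unox_auc, dtype=float)
    if (np.any(ox < 0)) or (np.any(unox < 0)):
        raise ValueError("AUC sums must be non-negative")
    total = ox + unox
    # ratio before scaling keeps the result inside [0, 100] exactly
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, (ox / np.where(total > 0, total, 1.0)) * 100.0, np.nan)
    if pct.ndim == 0:
        return float(pct)
    return pct


def pair_peptidoforms(
    table: pd.DataFrame,
    protein_acc: str,
    peptide_pool: Sequence[str],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample oxidized/unoxidized AUC sums for a protein's peptide pool.

    Missing AUCs contribute 0 to the sums but are tracked: ``censored`` is
    True where every oxidized form of the pool is missing while some
    unoxidized form was detected. Pool sequences absent from the table in
    both forms are dropped with a warning.
    """
    if samples is None:
        samples = sample_columns(table)
    sub = table[table["protein"] == protein_acc]
    kept: list[str] = []
    ox_rows, unox_rows = [], []
    for seq in peptide_pool:
        forms = sub[sub["bare_sequence"] == seq]
        if forms.empty:
            logger.warning(
                "pool sequence %s absent for protein %s in both forms; dropped",
                seq, protein_acc,
            )
            continue
        kept.append(seq)
        oxidized = forms["mods"].map(lambda m: len(msox_sites(m)) > 0)
        ox_rows.append(forms[oxidized][list(samples)])
        unox_rows.append(forms[~oxidized][list(samples)])
    if not kept:
        raise ValueError(
            f"no pool sequence found for protein {protein_acc!r}: {list(peptide_pool)}"
        )
    ox = pd.concat(ox_rows) if ox_rows else pd.DataFrame(columns=list(samples))
    unox = pd.concat(unox_rows) if unox_rows else pd.DataFrame(columns=list(samples))

    ox_sum = ox.sum(skipna=True) if len(ox) else pd.Series(0.0, index=list(samples))
    unox_sum = unox.sum(skipna=True) if len(unox) else pd.Series(0.0, index=list(samples))
    ox_detected = ox.notna().any() if len(ox) else pd.Series(False, index=list(samples))
    unox_detected = unox.notna().any() if len(unox) else pd.Series(False, index=list(samples))

    out = pd.DataFrame(
        {
            "sample": list(samples),
            "ox_auc": ox_sum.reindex(list(samples)).fillna(0.0).to_numpy(dtype=float),
            "unox_auc": unox_sum.reindex(list(samples)).fillna(0.0).to_numpy(dtype=float),
            "censored": (~ox_detected & unox_detected).reindex(list(samples)).to_numpy(),
        }
    )
    out.attrs["peptide_pool"] = kept
    out.attrs["protein"] = protein_acc
    return out


def occupancy_table(
    pairs: pd.DataFrame,
    censored_policy: str = "zero",
) -> pd.DataFrame:
    """Attach per-sample occupancy % to a pair_peptidoforms frame.

    ``censored_policy``: "zero" keeps censored samples at 0% (flagged);
    "exclude" sets their occupancy to NaN so they drop from group means.
    """
    if censored_policy not in ("zero", "exclude"):
        raise ValueError(f"unknown censored_policy {censored_policy!r}")
    out = pairs.copy()
    out["occupancy_pct"] = occupancy_percent(
        out["ox_auc"].to_numpy(), out["unox_auc"].to_numpy()
    )
    if censored_policy == "exclude":
        out.loc[out["censored"], "occupancy_pct"] = np.nan
    return out


def cohens_d(occ_a, occ_b) -> EffectSize:
    """Cohen's d between two occupancy samples (pooled SD, n_a+n_b−2 dof).

    Positive d means group b exceeds group a. Zero pooled SD with unequal
    means yields signed infinity.
    """
    a = np.asarray(occ_a, dtype=float)
    b = np.asarray(occ_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need ≥2 finite values per group for Cohen's d")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    diff = b.mean() - a.mean()
    if pooled == 0:
        d = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    else:
        d = float(diff / pooled)
    return EffectSize(
        d=d,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
        pooled_sd=float(pooled),
    )


def auc_change_percent(value_t1: float, value_t2: float) -> float:
    """Percent change from a baseline AUC: 100 × (t2 − t1)/t1."""
    if value_t1 < 0 or value_t2 < 0:
        raise ValueError("AUC values must be non-negative")
    if value_t1 == 0:
        return float("nan")
    return 100.0 * (value_t2 - value_t1) / value_t1
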
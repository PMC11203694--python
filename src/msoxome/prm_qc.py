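"""PRM assay QC: calibration-curve linearity and standard stability.

Targeted (parallel reaction monitoring) assays for synthetic peptide
standards are validated on a concentration ladder by ordinary least
squares of AUC on concentration, gated at R² ≥ 0.996. Spontaneous
(background) oxidation of an unmodified standard is the same
stoichiometry formula used for biological occupancy,
100 × ox/(ox + unox), tracked over storage months and summarised as
mean / SD / CV / max absolute drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

# background oxidation of an unmodified standard IS pool occupancy:
# one shared implementation.
from .occupancy import occupancy_percent as background_oxidation  # noqa: F401

DEFAULT_R2_GATE = 0.996

OX = "OX"
UNOX = "UNOX"


@dataclass(frozen=True)
class StandardCurve:
    peptide: str
    concentrations: tuple  # fmol/µL
    aucs: tuple
    slope: float
    intercept: float
    r2: float

    def passes(self, r2_gate: float = DEFAULT_R2_GATE) -> bool:
        return self.r2 >= r2_gate


@dataclass(frozen=True)
class StabilitySummary:
    peptide: str
    mean_pct: float
    sd_pct: float
    cv_pct: float
    max_abs_drift: float
    n: int


def fit_standard_curve(
    concentrations,
    aucs,
    peptide: str = "",
    weighted: bool = False,
) -> StandardCurve:
    """OLS fit of AUC on concentration for one peptide standard.

    Needs ≥3 points over ≥2 distinct, strictly positive concentrations.
    ``weighted=True`` uses 1/x weights, down-weighting the top of a wide
    ladder; R² is then computed on the weighted residuals.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(aucs, dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and AUC vectors differ in length")
    if x.size < 3:
        raise ValueError(f"need ≥3 calibration points, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.unique(x).size < 2:
        raise ValueError("need ≥2 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValueError("constant AUC across the ladder: R² undefined")
    if weighted:
        w = 1.0 / x
        W = np.diag(w)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        slope, intercept = float(beta[0]), float(beta[1])
        resid = y - (slope * x + intercept)
        ybar = np.average(y, weights=w)
        r2 = 1.0 - np.sum(w * resid**2) / np.sum(w * (y - ybar) ** 2)
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    return StandardCurve(
        peptide=peptide,
        concentrations=tuple(x),
        aucs=tuple(y),
        slope=slope,
        intercept=intercept,
        r2=float(r2),
    )


def stability_summary(background_pcts, peptide: str = "") -> StabilitySummary:
    """Mean/SD/CV and max absolute drift of background oxidation over time."""
    v = np.asarray(background_pcts, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need ≥2 observations for a stability summary")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else float("nan")
    drift = float(np.max(np.abs(v - mean)))
    return StabilitySummary(
        peptide=peptide, mean_pct=mean, sd_pct=sd, cv_pct=cv,
        max_abs_drift=drift, n=int(v.size),
    )


# ---------------------------------------------------------------------------
# table-level entry points (manual-integration AUC exports)


def read_prm_calibration(path: str | Path) -> pd.DataFrame:
    """Read a calibration table: peptide, species {OX, UNOX}, concentration, auc."""
    t = pd.read_csv(path, sep="\t")
    required = {"peptide", "species", "concentration", "auc"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return t


def read_prm_stability(path: str | Path) -> pd.DataFrame:
    """Read a stability table: peptide, month, species {OX, UNOX}, auc."""
    t = pd.read_csv(path, sep="\t")
    required = {"peptide", "month", "species", "auc"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return t


def calibration_curves(
    calibration: pd.DataFrame, weighted: bool = False
) -> dict[tuple[str, str], StandardCurve]:
    """Fit one standard curve per (peptide, species) in a calibration table."""
    curves = {}
    for (pep, species), grp in calibration.groupby(["peptide", "species"]):
        curves[(pep, species)] = fit_standard_curve(
            grp["concentration"], grp["auc"], peptide=f"{pep}/{species}",
            weighted=weighted,
        )
    return curves


def stability_series(stability: pd.DataFrame) -> pd.DataFrame:
    """Per (peptide, month) background oxidation % from OX/UNOX AUC pairs."""
    for pep, grp in stability.groupby("peptide"):
        ms = list(dict.fromkeys(grp["month"]))  # order of appearance
        if any(m < 0 for m in ms):
            raise ValueError(f"negative storage month for {pep!r}")
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError(f"storage months for {pep!r} must be strictly increasing")
    wide = stability.pivot_table(
        index=["peptide", "month"], columns="species", values="auc", aggfunc="sum"
    ).reset_index()
    for col in (OX, UNOX):
        if col not in wide:
            wide[col] = 0.0
    wide["background_ox_pct"] = background_oxidation(
        wide[OX].to_numpy(), wide[UNOX].to_numpy()
    )
    return wide.rename(columns={OX: "ox_auc", UNOX: "unox_auc"})


def qc_report(
    calibration: pd.DataFrame,
    stability: pd.DataFrame,
    r2_gate: float = DEFAULT_R2_GATE,
    weighted: bool = False,
) -> dict:
    """Full PRM QC report: curves with gates plus stability summaries."""
    curves = calibration_curves(calibration, weighted=weighted)
    series = stability_series(stability)
    summaries = {
        pep: stability_summary(grp["background_ox_pct"], peptide=pep)
        for pep, grp in series.groupby("peptide")
    }
    return {
        "r2_gate": r2_gate,
        "curves": [
            {
                "peptide": pep,
                "species": species,
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r2,
                "passes": c.passes(r2_gate),
            }
            for (pep, species), c in sorted(curves.items())
        ],
        "stability": [
            {
                "peptide": s.peptide,
                "mean_pct": s.mean_pct,
                "sd_pct": s.sd_pct,
                "cv_pct": s.cv_pct,
                "max_abs_drift": s.max_abs_drift,
                "n": s.n,
            }
            for s in summaries.values()
        ],
    }
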
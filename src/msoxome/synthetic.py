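"""Synthetic label-free MSox study generator with known ground truth.

Emulates the study design the pipeline targets: three time-point batches
(3, 6, 9 months), each with 16 mice (8 wild-type C57BL/6 and 8 5XFAD
transgenics, balanced for sex), peptide-level AUC matrices with
log-normal protein abundance, per-protein methionine-sulfoxide occupancy
with genotype/time effects, multiplicative AUC noise, and censoring at a
lower limit of detection. Batch-specific intensity shifts are confounded
with time point by construction, so cross-batch quantitative comparison
is invalid on this data exactly as it is on the real design.

Noise acts at the AUC level (each peptidoform species is perturbed
independently), so occupancy estimates inherit realistic error and
censoring interacts with stoichiometry: low-occupancy oxidized forms
fall below the LOD first.

All randomness flows from ``SimConfig.seed``; the same configuration
reproduces identical tables byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import (
    AnnotationSets,
    StudyDesign,
    parse_matrix_frame,
    render_peptidoform,
    write_gmt,
)

WT = "WT"
FAD = "FAD5X"

#: residues used for random tryptic-like peptides (Met inserted separately)
_RESIDUES = "ACDEFGHIKLNPQRSTVWY"

#: concentration ladder for PRM linearity studies, fmol/µL
PRM_LADDER = (0.1, 0.5, 1.0, 10.0, 25.0, 50.0, 100.0)

#: storage time points (months) for standard stability
PRM_MONTHS = (0, 1, 2, 6, 11)

#: APOE-like standards with their long-run background oxidation levels (%)
PRM_STANDARDS = {"LGADMEDLR": 1.63, "NEVHTMLGQSTEEIR": 4.20}


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults encode the target study's conditions: 8 mice per
    genotype per time point, baseline Met-site occupancy 6.7% with a
    +10.4 percentage-point 5XFAD shift at 9 months (17.1% total) and a
    smaller +3 shift at 6 months; AUC noise cv = 0.21, calibrated so a
    two-peptide pool's per-group occupancy spread pools to ≈ 2.3
    percentage points at those occupancy levels; per-batch log2 intensity
    offsets confounded with age.
    """

    n_proteins: int = 150
    peptides_per_protein: tuple[int, int] = (2, 5)  # uniform inclusive range
    met_fraction: float = 0.20
    baseline_occupancy_pct: float = 6.7
    occupancy_effects: dict = field(
        default_factory=lambda: {(FAD, "6m"): 3.0, (FAD, "9m"): 10.4}
    )
    n_induced_proteins: int = 6
    induced_wt_occupancy_pct: float = 1.0
    induced_fad_occupancy_pct: float = 25.0
    protein_abundance_log2_mean: float = 20.0
    protein_abundance_log2_sd: float = 2.0
    peptide_offset_log2_sd: float = 1.0
    noise_cv: float = 0.21
    lod: float = 32768.0  # 2**15, censors low-abundance oxidized forms
    batch_shift_log2: dict = field(
        default_factory=lambda: {"3m": 0.0, "6m": 0.6, "9m": -0.4}
    )
    timepoints: tuple[str, ...] = ("3m", "6m", "9m")
    n_per_group: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.met_fraction <= 1:
            raise ValueError("met_fraction must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be an increasing positive range")
        if self.n_per_group % 2:
            raise ValueError("n_per_group must be even for a sex-balanced design")


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    peptides: pd.DataFrame  # peptide, protein, has_met, induced
    true_occupancy: pd.DataFrame  # proteins × samples, percent
    true_abundance: pd.DataFrame  # peptides × samples, pre-noise total AUC
    censored: pd.DataFrame  # observed-matrix rows × samples, bool


@dataclass
class StudyData:
    matrices: dict  # timepoint -> DataFrame in the ingest file schema
    design: StudyDesign
    truth: GroundTruth
    annotations: AnnotationSets


def _make_design(config: SimConfig) -> StudyDesign:
    rows = []
    half = config.n_per_group // 2
    for tp in config.timepoints:
        for geno in (WT, FAD):
            for i in range(config.n_per_group):
                sex = "F" if i < half else "M"
                rows.append(
                    {
                        "sample_id": f"{tp}_{geno}_{sex}{(i % half) + 1}",
                        "genotype": geno,
                        "sex": sex,
                        "timepoint": tp,
                        "batch": f"B{tp}",
                    }
                )
    return StudyDesign(pd.DataFrame(rows))


def _random_peptide(rng: np.random.Generator, with_met: bool) -> str:
    length = int(rng.integers(8, 16))
    body = "".join(rng.choice(list(_RESIDUES), size=length - 1))
    if with_met:
        pos = int(rng.integers(0, length - 1))
        body = body[:pos] + "M" + body[pos:]
        body = body[: length - 1]
        if "M" not in body:  # M may have been truncated off the tail
            body = "M" + body[1:]
    return body + ("K" if rng.random() < 0.5 else "R")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _true_occupancy(config: SimConfig, protein_idx: int, induced: bool,
                    genotype: str, timepoint: str) -> float:
    if induced:
        occ = (
            config.induced_fad_occupancy_pct
            if genotype == FAD
            else config.induced_wt_occupancy_pct
        )
    else:
        occ = config.baseline_occupancy_pct + config.occupancy_effects.get(
            (genotype, timepoint), 0.0
        )
    return float(min(max(occ, 0.0), 100.0))


def simulate_study(config: SimConfig | None = None, seed: int | None = None) -> StudyData:
    """Generate per-batch peptide matrices, the design, and ground truth.

    For every Met-containing peptide two observed rows exist: the
    unoxidized form and the singly oxidized form (``[M]`` at the first
    methionine), with expected AUCs total × (1 − occ/100) and
    total × occ/100, independently perturbed by log-normal noise and then
    censored at the LOD (censored values are missing, not zero).
    """
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)

    lo, hi = config.peptides_per_protein
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]
    induced = {
        p: (i < config.n_induced_proteins and config.met_fraction > 0)
        for i, p in enumerate(proteins)
    }

    pep_rows = []
    seen: set[str] = set()
    for pi, prot in enumerate(proteins):
        n_pep = int(rng.integers(lo, hi + 1))
        # induced proteins must carry a Met peptide to show an effect
        for j in range(n_pep):
            with_met = bool(rng.random() < config.met_fraction) or (
                induced[prot] and j == 0
            )
            seq = _random_peptide(rng, with_met)
            while seq in seen:
                seq = _random_peptide(rng, with_met)
            seen.add(seq)
            pep_rows.append(
                {
                    "peptide": seq,
                    "protein": prot,
                    "has_met": "M" in seq,
                    "induced": induced[prot],
                    "abundance_log2": rng.normal(
                        config.protein_abundance_log2_mean
                        # oxidation-induced targets mimic high-abundance
                        # neuroinflammation proteins, keeping their oxidized
                        # forms above the LOD in both genotypes
                        + (3.0 if induced[prot] else 0.0),
                        config.protein_abundance_log2_sd,
                    )
                    if j == 0
                    else np.nan,  # filled below from protein level
                }
            )
    peptides = pd.DataFrame(pep_rows)
    # protein-level abundance shared by its peptides, plus per-peptide offset
    prot_abund = peptides.groupby("protein")["abundance_log2"].first()
    peptides["abundance_log2"] = peptides["protein"].map(prot_abund) + rng.normal(
        0.0, config.peptide_offset_log2_sd, size=len(peptides)
    )

    samples = design.sample_ids
    sample_meta = design.table.set_index("sample_id")

    occ = pd.DataFrame(index=proteins, columns=samples, dtype=float)
    for s in samples:
        geno = sample_meta.loc[s, "genotype"]
        tp = sample_meta.loc[s, "timepoint"]
        occ[s] = [
            _true_occupancy(config, i, induced[p], geno, tp)
            for i, p in enumerate(proteins)
        ]

    abund = pd.DataFrame(index=peptides["peptide"], columns=samples, dtype=float)
    matrices: dict[str, pd.DataFrame] = {}
    censored_frames = []

    for tp in config.timepoints:
        tp_samples = design.samples(timepoint=tp)
        shift = config.batch_shift_log2.get(tp, 0.0)
        obs_rows = []
        cens_rows = []
        for r in peptides.itertuples(index=False):
            total = 2.0 ** (r.abundance_log2 + shift)
            abund.loc[r.peptide, tp_samples] = total
            p_occ = occ.loc[r.protein, tp_samples].to_numpy(dtype=float)
            if r.has_met:
                frac_ox = p_occ / 100.0
                mpos = r.peptide.index("M") + 1
                forms = [
                    (r.peptide, total * (1.0 - frac_ox)),
                    (
                        render_peptidoform(r.peptide, {(mpos, "MSOX")}),
                        total * frac_ox,
                    ),
                ]
            else:
                forms = [(r.peptide, np.full(len(tp_samples), total))]
            for name, expected in forms:
                noisy = np.asarray(expected, dtype=float) * _lognormal_noise(
                    rng, config.noise_cv, len(tp_samples)
                )
                cens = noisy < config.lod
                vals = np.where(cens, np.nan, noisy)
                row = {"peptide": name, "protein": r.protein,
                       "score": float(np.round(rng.uniform(20, 60), 2))}
                row.update(dict(zip(tp_samples, vals)))
                obs_rows.append(row)
                crow = {"peptide": name, "timepoint": tp}
                crow.update(dict(zip(tp_samples, cens)))
                cens_rows.append(crow)
        matrices[tp] = pd.DataFrame(obs_rows)
        censored_frames.append(pd.DataFrame(cens_rows))

    annotations = _make_annotations(peptides, induced, rng)
    truth = GroundTruth(
        peptides=peptides,
        true_occupancy=occ,
        true_abundance=abund,
        censored=pd.concat(censored_frames, ignore_index=True),
    )
    return StudyData(matrices=matrices, design=design, truth=truth, annotations=annotations)


def _make_annotations(
    peptides: pd.DataFrame, induced: dict, rng: np.random.Generator,
    n_random_terms: int = 12,
) -> AnnotationSets:
    """GMT-style sets over the simulated proteome with one planted term.

    The planted term collects the oxidation-induced proteins (plus a few
    bystanders) so enrichment has a known positive; the remaining terms
    are random draws and should stay at chance.
    """
    proteins = sorted(peptides["protein"].unique())
    induced_accs = sorted(p for p in proteins if induced[p])
    sets = {}
    if induced_accs:
        bystanders = [p for p in proteins if not induced[p]]
        extra = list(rng.choice(bystanders, size=min(4, len(bystanders)), replace=False))
        sets["T_PLANTED"] = ("oxidation-induced module", frozenset(induced_accs + extra))
    for t in range(n_random_terms):
        size = int(rng.integers(5, max(6, len(proteins) // 5)))
        members = rng.choice(proteins, size=min(size, len(proteins)), replace=False)
        sets[f"T{t:03d}"] = (f"random module {t}", frozenset(members))
    return AnnotationSets(sets)


def study_table(data: StudyData, timepoint: str) -> "pd.DataFrame":
    """Ingest one simulated batch matrix into the internal peptidoform table."""
    return parse_matrix_frame(
        data.matrices[timepoint], data.design, timepoint=timepoint,
        source=f"simulated:{timepoint}",
    )


def apoe_like_config(seed: int = 0, **overrides) -> SimConfig:
    """A small single-batch configuration for occupancy recovery studies.

    Models a handful of high-abundance proteins quantified by a
    two-peptide pool at 9 months: wild-type occupancy 6.7%, 5XFAD 17.1%
    (+10.4 points), 8 mice per genotype. High abundance keeps both
    species well above the LOD, so recovery error reflects AUC noise
    alone, as it does for an abundant biomarker protein.
    """
    params = dict(
        n_proteins=6,
        peptides_per_protein=(2, 2),
        met_fraction=1.0,
        n_induced_proteins=0,
        protein_abundance_log2_mean=24.0,
        timepoints=("9m",),
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# PRM fixtures


def simulate_prm(
    ladder=PRM_LADDER,
    noise_cv: float = 0.01,
    background_ox_pct: dict | None = None,
    months=PRM_MONTHS,
    drift_sd_pct: float = 0.15,
    stability_concentration: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic PRM calibration and storage-stability tables.

    Calibration AUC is proportional to concentration with multiplicative
    noise for both the unmodified and oxidized species of each standard.
    Stability rows hold the stated background oxidation plus a small
    month-to-month drift, measured at a fixed mid-ladder concentration.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    ladder = tuple(ladder)
    if not ladder or any(c <= 0 for c in ladder):
        raise ValueError("ladder must be non-empty with positive concentrations")
    if background_ox_pct is None:
        background_ox_pct = dict(PRM_STANDARDS)
    rng = np.random.default_rng(seed)

    cal_rows = []
    stab_rows = []
    for pep, bg in background_ox_pct.items():
        for species in ("UNOX", "OX"):
            slope = float(rng.uniform(5e3, 5e4))
            noise = _lognormal_noise(rng, noise_cv, len(ladder))
            for conc, eps in zip(ladder, noise):
                cal_rows.append(
                    {
                        "peptide": pep,
                        "species": species,
                        "concentration": conc,
                        "auc": slope * conc * eps,
                    }
                )
        unox_slope = float(rng.uniform(5e3, 5e4))
        for month in months:
            bg_m = bg + float(rng.normal(0.0, drift_sd_pct))
            bg_m = min(max(bg_m, 0.0), 100.0)
            unox = unox_slope * stability_concentration * float(
                _lognormal_noise(rng, noise_cv, 1)[0]
            )
            ox = unox * bg_m / (100.0 - bg_m) if bg_m < 100 else unox
            stab_rows.append(
                {"peptide": pep, "month": month, "species": "UNOX", "auc": unox}
            )
            stab_rows.append(
                {"peptide": pep, "month": month, "species": "OX", "auc": ox}
            )
    return pd.DataFrame(cal_rows), pd.DataFrame(stab_rows)


# ---------------------------------------------------------------------------
# fixture writing


def write_study(data: StudyData, outdir: str | Path, float_format: str = "%.6g") -> dict:
    """Write the full fixture set (matrices, design, GMT) as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tp, mat in data.matrices.items():
        p = outdir / f"matrix_{tp}.tsv"
        mat.to_csv(p, sep="\t", index=False, float_format=float_format)
        paths[f"matrix_{tp}"] = p
    p = outdir / "design.tsv"
    data.design.table.to_csv(p, sep="\t", index=False)
    paths["design"] = p
    p = outdir / "annotations.gmt"
    write_gmt(p, data.annotations)
    paths["annotations"] = p
    return paths


def write_prm(
    calibration: pd.DataFrame,
    stability: pd.DataFrame,
    outdir: str | Path,
    float_format: str = "%.6g",
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cal = outdir / "prm_calibration.tsv"
    stab = outdir / "prm_stability.tsv"
    calibration.to_csv(cal, sep="\t", index=False, float_format=float_format)
    stability.to_csv(stab, sep="\t", index=False, float_format=float_format)
    return {"calibration": cal, "stability": stab}
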
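"""End-to-end orchestration: ingest → speciation → differential →
occupancy → enrichment → PRM QC, driven by one configuration.

Every stage's row counts are logged; quantitative stages only ever
compare samples within one acquisition batch (time point). Outputs are
plain TSV/JSON with floats at six significant digits, so identical
inputs and configuration give byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import differential_table, select_enrichment_input
from .enrichment import enrich
from .ingest import (
    StudyDesign,
    apply_id_filters,
    msox_sites,
    read_design,
    read_gmt,
    read_peptide_matrix,
    sample_columns,
)
from .occupancy import cohens_d, occupancy_table, pair_peptidoforms
from .prm_qc import qc_report, read_prm_calibration, read_prm_stability
from .speciation import (
    classify_targets,
    coverage_stats,
    coverage_table,
    extract_msox,
    msox_proteins,
    temporal_overlap,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

WT = "WT"
FAD = "FAD5X"


@dataclass
class RunConfig:
    design: str
    matrices: dict  # timepoint -> path
    gmt: str | None = None
    prm_calibration: str | None = None
    prm_stability: str | None = None
    outdir: str = "msoxome_out"
    dialect: str | None = None
    min_score: float | None = 15.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    p_max: float = 0.1
    log2fc_min: float = 4.0
    q_max: float = 0.05
    min_n: int = 3
    on_log2: bool = True
    equal_var: bool = True
    venn_mode: str = "detected"  # or "significant"
    censored_policy: str = "zero"
    occupancy_proteins: list = field(default_factory=list)  # [] = auto-select
    max_auto_occupancy_proteins: int = 5
    r2_gate: float = 0.996
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if self.venn_mode not in ("detected", "significant"):
            raise ValueError(f"unknown venn_mode {self.venn_mode!r}")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        if self.fc_down >= self.fc_up:
            raise ValueError("fc_down must be < fc_up")
        for label, p in self.input_paths().items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")

    def input_paths(self) -> dict:
        paths = {"design": self.design}
        paths.update({f"matrix_{tp}": p for tp, p in self.matrices.items()})
        for label in ("gmt", "prm_calibration", "prm_stability"):
            p = getattr(self, label)
            if p is not None:
                paths[label] = p
        return paths


def validate_design(design: StudyDesign, tables: dict) -> dict:
    """Check sample/column agreement and group balance per batch.

    Returns ``{"errors": [...], "warnings": [...]}``; column mismatches
    are errors, unbalanced genotype/sex groups are warnings.
    """
    errors: list[str] = []
    warnings: list[str] = []
    for tp, table in tables.items():
        expected = set(design.samples(timepoint=tp))
        got = set(sample_columns(table))
        missing = expected - got
        extra = got - expected - set(design.sample_ids)
        if missing:
            errors.append(f"{tp}: design samples absent from matrix: {sorted(missing)}")
        if extra:
            errors.append(f"{tp}: matrix columns not in design: {sorted(extra)}")
    for tp in design.timepoints:
        counts = (
            design.table[design.table["timepoint"] == tp]
            .groupby(["genotype", "sex"])["sample_id"]
            .count()
        )
        if counts.nunique() > 1:
            warnings.append(
                f"{tp}: unbalanced genotype×sex groups: {counts.to_dict()}"
            )
    return {"errors": errors, "warnings": warnings}


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}") if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _auto_occupancy_proteins(msox_tables: dict, full_tables: dict, limit: int) -> list[str]:
    """Pick proteins whose oxidized and unoxidized forms are both well
    detected (candidate stoichiometry targets), ranked by total AUC."""
    scores: dict[str, float] = {}
    for tp, msox in msox_tables.items():
        full = full_tables[tp]
        samples = sample_columns(full)
        ox_prots = set(msox["protein"])
        unox = full[
            full["mods"].map(lambda m: not msox_sites(m))
            & full["protein"].isin(ox_prots)
        ]
        for prot, grp in unox.groupby("protein"):
            scores[prot] = scores.get(prot, 0.0) + float(
                np.nansum(grp[samples].to_numpy(dtype=float))
            )
    ranked = sorted(scores, key=lambda p: (-scores[p], p))
    return ranked[:limit]


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the consolidated report bundle.

    Returns a manifest dict (also written as ``run_manifest.json``).
    Any stage failure aborts with the stage name in the exception message.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        design = read_design(config.design)
        full_tables: dict[str, pd.DataFrame] = {}
        for tp, path in config.matrices.items():
            table = read_peptide_matrix(
                path, design, dialect=config.dialect, timepoint=tp
            )
            full_tables[tp] = apply_id_filters(table, min_score=config.min_score)
        report = validate_design(design, full_tables)
        if report["errors"]:
            raise ValueError(f"design validation failed: {report['errors']}")

        stage = "speciation"
        msox_tables = {tp: extract_msox(t) for tp, t in full_tables.items()}
        stats = []
        for tp in config.matrices:
            for geno in (WT, FAD):
                group = design.samples(timepoint=tp, genotype=geno)
                if not group:
                    continue
                stats.append(
                    coverage_stats(
                        msox_tables[tp], full_tables[tp], group, f"{tp}/{geno}"
                    )
                )
        cov = coverage_table(stats)
        cov.to_csv(outdir / "coverage.tsv", sep="\t", index=False,
                   float_format=FLOAT_FORMAT)

        stage = "differential"
        diffs = {}
        for tp in config.matrices:
            diffs[tp] = differential_table(
                msox_tables[tp], design, tp,
                fc_up=config.fc_up, fc_down=config.fc_down, p_max=config.p_max,
                on_log2=config.on_log2, equal_var=config.equal_var,
                min_n=config.min_n,
            )
            diffs[tp].to_csv(
                outdir / f"differential_{tp}.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )

        stage = "speciation:venn"
        if config.venn_mode == "detected":
            protein_sets = {tp: msox_proteins(msox_tables[tp]) for tp in config.matrices}
        else:
            protein_sets = {
                tp: set(d.loc[d["call"].isin(["UP", "DOWN"]), "protein"])
                for tp, d in diffs.items()
            }
        partition = temporal_overlap(protein_sets)
        with open(outdir / "venn.json", "w", encoding="utf-8") as fh:
            json.dump(_round_floats(partition.to_dict()), fh, indent=2, sort_keys=True)
        targets = classify_targets(partition)
        target_rows = [
            {"protein": p, "class": cls}
            for cls in ("CONSTANT", "DYNAMIC")
            for p in sorted(targets[cls])
        ]
        pd.DataFrame(target_rows, columns=["protein", "class"]).to_csv(
            outdir / "targets.tsv", sep="\t", index=False
        )

        stage = "enrichment"
        enrich_frames = []
        if config.gmt is not None:
            sets = read_gmt(config.gmt)
            for tp in config.matrices:
                selected = select_enrichment_input(
                    diffs[tp], log2fc_min=config.log2fc_min, p_max=config.p_max
                )
                background = set(full_tables[tp]["protein"])
                target = set(selected["protein"]) & background
                res = enrich(target, background, sets, q_max=config.q_max)
                res.insert(0, "timepoint", tp)
                enrich_frames.append(res)
            pd.concat(enrich_frames, ignore_index=True).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )

        stage = "occupancy"
        occ_proteins = list(config.occupancy_proteins) or _auto_occupancy_proteins(
            msox_tables, full_tables, config.max_auto_occupancy_proteins
        )
        occ_rows, effect_rows = [], []
        for prot in occ_proteins:
            for tp in config.matrices:
                table = full_tables[tp]
                # pool = sequences observed in oxidized form, paired with
                # their unoxidized counterparts in the full table
                msox = msox_tables[tp]
                pool = sorted(
                    set(msox.loc[msox["protein"] == prot, "bare_sequence"])
                )
                if not pool:
                    continue
                pairs = pair_peptidoforms(table, prot, pool)
                occ = occupancy_table(pairs, censored_policy=config.censored_policy)
                occ.insert(0, "timepoint", tp)
                occ.insert(0, "protein", prot)
                occ_rows.append(occ)
                by_sample = occ.set_index("sample")["occupancy_pct"]
                wt = by_sample.reindex(design.samples(timepoint=tp, genotype=WT))
                fad = by_sample.reindex(design.samples(timepoint=tp, genotype=FAD))
                if wt.notna().sum() >= 2 and fad.notna().sum() >= 2:
                    es = cohens_d(wt.dropna(), fad.dropna())
                    effect_rows.append(
                        {
                            "protein": prot, "timepoint": tp, "d": es.d,
                            "mean_wt": es.mean_a, "mean_fad": es.mean_b,
                            "n_wt": es.n_a, "n_fad": es.n_b,
                            "pooled_sd": es.pooled_sd,
                        }
                    )
        if occ_rows:
            pd.concat(occ_rows, ignore_index=True).to_csv(
                outdir / "occupancy.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
        pd.DataFrame(
            effect_rows,
            columns=["protein", "timepoint", "d", "mean_wt", "mean_fad",
                     "n_wt", "n_fad", "pooled_sd"],
        ).to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False,
                 float_format=FLOAT_FORMAT)

        stage = "prm_qc"
        if config.prm_calibration is not None and config.prm_stability is not None:
            cal = read_prm_calibration(config.prm_calibration)
            stab = read_prm_stability(config.prm_stability)
            rep = qc_report(cal, stab, r2_gate=config.r2_gate)
            with open(outdir / "prm_qc_report.json", "w", encoding="utf-8") as fh:
                json.dump(_round_floats(rep), fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _round_floats(
            {k: (dict(v) if isinstance(v, dict) else v) for k, v in vars(config).items()}
        ),
        "inputs": {
            label: _sha256(path) for label, path in config.input_paths().items()
        },
        "design_validation": report,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
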
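"""Readers and parsers for peptide-level label-free quantification exports.

The working in-memory container is a :class:`pandas.DataFrame` with one row
per peptidoform (a peptide sequence together with its methionine-sulfoxide
site set) and the metadata columns

``peptidoform`` (rendered string), ``bare_sequence``, ``mods``
(frozenset of ``(position, mod)`` pairs), ``protein``, optionally
``gene`` and ``score``, followed by one abundance (AUC) column per sample.

Missing abundances are ``NaN``. An AUC of 0 is normalised to ``NaN`` at
ingest: label-free zero intensities mean "not detected", not "measured as
zero" — intensities below the lower limit of detection are censored.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# modification labels
MSOX = "MSOX"
CARBAMIDOMETHYL = "CARBAMIDOMETHYL"
OTHER = "OTHER"

# parsing dialects
BRACKET = "BRACKET"
PEAKS_DELTA = "PEAKS_DELTA"

META_COLUMNS = ("peptidoform", "bare_sequence", "mods", "protein", "gene", "score")

_DELTA_RE = re.compile(r"\(([+-]\d+(?:\.\d+)?)\)")

#: delta masses (Da) mapped to named modifications; anything else is OTHER
_DELTA_NAMES = {15.99: MSOX, 57.02: CARBAMIDOMETHYL}


class PeptidoformParseError(ValueError):
    """Malformed modified-peptide string."""


class PeptidoformValidationError(ValueError):
    """Structurally valid string carrying an impossible modification."""


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


@dataclass(frozen=True)
class PeptidoformRecord:
    """One peptide species: sequence, modification set, parent protein, AUCs."""

    bare_sequence: str
    mods: frozenset  # of (1-based position, mod name)
    protein_acc: str
    auc: Mapping[str, float]
    gene_symbol: str | None = None
    id_score: float | None = None

    def __post_init__(self) -> None:
        n = len(self.bare_sequence)
        for pos, mod in self.mods:
            if not 1 <= pos <= n:
                raise PeptidoformValidationError(
                    f"modification position {pos} outside 1..{n} for {self.bare_sequence!r}"
                )
            if mod == MSOX and self.bare_sequence[pos - 1] != "M":
                raise PeptidoformValidationError(
                    f"MSOX at position {pos} of {self.bare_sequence!r} is not a methionine"
                )

    @property
    def is_msox(self) -> bool:
        return any(mod == MSOX for _, mod in self.mods)


@dataclass
class StudyDesign:
    """Sample → (genotype, sex, timepoint, batch) mapping.

    Each time point was processed as a single batch; quantitative
    comparisons are only valid within one batch.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "genotype", "sex", "timepoint", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"design table missing columns: {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise SchemaError(f"duplicate sample ids in design: {dupes}")
        # each time point must map to exactly one batch
        tp_batches = self.table.groupby("timepoint")["batch"].nunique()
        bad = tp_batches[tp_batches > 1]
        if len(bad):
            raise SchemaError(
                f"time points spanning multiple batches: {sorted(bad.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for tp in self.table["timepoint"]:
            if tp not in seen:
                seen.append(tp)
        return seen

    def samples(
        self,
        timepoint: str | None = None,
        genotype: str | None = None,
        sex: str | None = None,
    ) -> list[str]:
        t = self.table
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        if genotype is not None:
            t = t[t["genotype"] == genotype]
        if sex is not None:
            t = t[t["sex"] == sex]
        return list(t["sample_id"])

    def batch_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return row["batch"].iloc[0]

    def batches_of(self, sample_ids: Iterable[str]) -> set[str]:
        return {self.batch_of(s) for s in sample_ids}


@dataclass
class AnnotationSets:
    """Gene-set annotations keyed by term id (GMT semantics)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise SchemaError(f"annotation term {term!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def name(self, term: str) -> str:
        return self.sets[term][0]


# ---------------------------------------------------------------------------
# peptidoform notation


def detect_dialect(text: str) -> str:
    """Guess the modification dialect of a modified-peptide string.

    ``(+`` marks a PEAKS delta-mass annotation, ``[`` the bracket notation
    for oxidized methionine. A string carrying both is ambiguous and needs
    an explicit dialect.
    """
    has_delta = "(+" in text or "(-" in text
    has_bracket = "[" in text
    if has_delta and has_bracket:
        raise PeptidoformParseError(
            f"ambiguous notation in {text!r}: both '[...]' and '(+...)' present; "
            "pass an explicit dialect"
        )
    if has_delta:
        return PEAKS_DELTA
    return BRACKET  # bracket parser also accepts plain sequences


def _classify_delta(delta: float) -> str:
    for mass, name in _DELTA_NAMES.items():
        if math.isclose(delta, mass, abs_tol=0.05):
            return name
    return OTHER


def parse_peptidoform(
    text: str, dialect: str | None = None
) -> tuple[str, frozenset]:
    """Parse a modified-peptide string into ``(bare_sequence, mods)``.

    ``mods`` is a frozenset of ``(1-based position, mod name)`` pairs.
    In the BRACKET dialect ``[M]`` denotes an oxidized methionine, e.g.
    ``"LGAD[M]EDLR"`` → ``("LGADMEDLR", {(5, MSOX)})``. In the PEAKS_DELTA
    dialect each residue may be followed by a ``(+mass)`` annotation, e.g.
    ``"LGADM(+15.99)EDLR"``; +15.99 on M is MSox, +57.02 on C is
    carbamidomethylation, anything else is carried as OTHER.
    """
    if not text:
        raise PeptidoformParseError("empty peptidoform string")
    if dialect is None:
        dialect = detect_dialect(text)
    if dialect == BRACKET:
        return _parse_bracket(text)
    if dialect == PEAKS_DELTA:
        return _parse_peaks_delta(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_residue(ch: str, text: str) -> None:
    if ch not in AMINO_ACIDS:
        raise PeptidoformParseError(f"invalid residue {ch!r} in {text!r}")


def _parse_bracket(text: str) -> tuple[str, frozenset]:
    bare: list[str] = []
    mods: set[tuple[int, str]] = set()
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j == -1:
                raise PeptidoformParseError(f"unclosed '[' at offset {i} in {text!r}")
            inner = text[i + 1 : j]
            if len(inner) != 1:
                raise PeptidoformParseError(
                    f"bracket token {text[i : j + 1]!r} in {text!r} must hold one residue"
                )
            _check_residue(inner, text)
            if inner != "M":
                raise PeptidoformValidationError(
                    f"oxidation bracket on non-methionine residue {inner!r} in {text!r}"
                )
            bare.append(inner)
            mods.add((len(bare), MSOX))
            i = j + 1
        elif ch == "]":
            raise PeptidoformParseError(f"unmatched ']' at offset {i} in {text!r}")
        else:
            _check_residue(ch, text)
            bare.append(ch)
            i += 1
    return "".join(bare), frozenset(mods)


def _parse_peaks_delta(text: str) -> tuple[str, frozenset]:
    bare: list[str] = []
    mods: set[tuple[int, str]] = set()
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            m = _DELTA_RE.match(text, i)
            if m is None:
                raise PeptidoformParseError(
                    f"malformed '(...)' annotation at offset {i} in {text!r}"
                )
            if not bare:
                raise PeptidoformParseError(
                    f"modification annotation before any residue in {text!r}"
                )
            delta = float(m.group(1))
            name = _classify_delta(delta)
            pos = len(bare)
            if name == MSOX and bare[-1] != "M":
                raise PeptidoformValidationError(
                    f"+15.99 (MSox) on non-methionine residue {bare[-1]!r} in {text!r}"
                )
            mods.add((pos, name))
            i = m.end()
        else:
            _check_residue(ch, text)
            bare.append(ch)
            i += 1
    return "".join(bare), frozenset(mods)


def render_peptidoform(bare_sequence: str, mods: Iterable[tuple[int, str]]) -> str:
    """Render ``(bare_sequence, mods)`` in the BRACKET dialect.

    Only MSox sites are rendered (``[M]``); carbamidomethylation is a fixed
    modification carried for bookkeeping but not part of peptidoform
    identity, so it is omitted from the rendered form.
    """
    msox_pos = {pos for pos, mod in mods if mod == MSOX}
    out = []
    for i, ch in enumerate(bare_sequence, start=1):
        out.append(f"[{ch}]" if i in msox_pos else ch)
    return "".join(out)


def msox_sites(mods: Iterable[tuple[int, str]]) -> frozenset[int]:
    return frozenset(pos for pos, mod in mods if mod == MSOX)


# ---------------------------------------------------------------------------
# file readers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype={0: str})


def read_design(path: str | Path) -> StudyDesign:
    """Read a sample-design TSV (sample_id, genotype, sex, timepoint, batch)."""
    return StudyDesign(_read_table(path))


def read_peptide_matrix(
    path: str | Path,
    design: StudyDesign,
    dialect: str | None = None,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Read a peptide abundance matrix into the internal peptidoform table.

    The file must have ``peptide`` and ``protein`` columns, an optional
    ``score`` column (PEAKS −10logP), and one column per design sample —
    per batch sample when ``timepoint`` is given, since each batch is
    acquired and exported separately. Zero or empty AUC cells become NaN
    (not detected). Duplicate rows with the same (bare sequence, MSox
    site set, protein) identity — e.g. charge states — are summed into
    one record, since species are quantified by total AUC.
    """
    return parse_matrix_frame(
        _read_table(path), design, dialect=dialect, timepoint=timepoint,
        source=str(path),
    )


def parse_matrix_frame(
    raw: pd.DataFrame,
    design: StudyDesign,
    dialect: str | None = None,
    timepoint: str | None = None,
    source: str = "<frame>",
) -> pd.DataFrame:
    """Convert an in-memory abundance matrix to the internal table.

    Same contract as :func:`read_peptide_matrix`, without the file I/O.
    """
    path = source
    if "peptide" not in raw.columns or "protein" not in raw.columns:
        raise SchemaError(
            f"{path}: expected 'peptide' and 'protein' columns, got {list(raw.columns)}"
        )
    if timepoint is not None:
        expected = design.samples(timepoint=timepoint)
    else:
        expected = design.sample_ids
        if any(s not in raw.columns for s in expected):
            # a single-batch export: accept iff exactly one batch matches
            for tp in design.timepoints:
                tp_samples = design.samples(timepoint=tp)
                if all(s in raw.columns for s in tp_samples):
                    expected = tp_samples
                    break
    missing = [s for s in expected if s not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: sample columns absent from file: {missing}")
    extra = [
        c
        for c in raw.columns
        if c not in ("peptide", "protein", "gene", "score")
        and c not in design.sample_ids
    ]
    if extra:
        raise SchemaError(f"{path}: columns not in design: {extra}")

    samples = list(expected)
    rows = []
    for _, r in raw.iterrows():
        bare, mods = parse_peptidoform(str(r["peptide"]), dialect)
        accs = re.split(r"[;,]", str(r["protein"]))
        protein = accs[0].strip()
        if len(accs) > 1:
            logger.info(
                "peptide %s: multiple accessions %s; keeping %s",
                r["peptide"], accs, protein,
            )
        row = {
            "peptidoform": render_peptidoform(bare, mods),
            "bare_sequence": bare,
            "mods": mods,
            "protein": protein,
            "gene": r.get("gene", None),
            "score": pd.to_numeric(r.get("score", np.nan)),
        }
        for s in samples:
            v = pd.to_numeric(r[s], errors="coerce")
            if pd.notna(v) and v < 0:
                raise SchemaError(f"{path}: negative AUC {v} for sample {s}")
            row[s] = np.nan if (pd.isna(v) or v == 0) else float(v)
        rows.append(row)

    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + samples)
    table = dedupe_peptidoforms(table, samples)
    return table.reset_index(drop=True)


def dedupe_peptidoforms(table: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Sum duplicate (bare sequence, MSox sites, protein) rows into one record.

    NaN-aware: a sample stays NaN only if it is missing in every duplicate.
    The best (max) id score is kept.
    """
    cols = list(META_COLUMNS) + list(samples)
    table = table.reset_index(drop=True)
    key = pd.Series(
        [
            (r.bare_sequence, msox_sites(r.mods), r.protein)
            for r in table.itertuples(index=False)
        ],
        index=table.index,
    )
    dup = key.duplicated(keep=False)
    if not dup.any():
        return table[cols]

    def _agg(group: pd.DataFrame) -> pd.Series:
        first = group.iloc[0]
        out = {c: first[c] for c in META_COLUMNS}
        out["score"] = group["score"].max()
        # identity ignores carbamidomethyl: merge mods so MSOX sites survive
        out["mods"] = frozenset().union(*group["mods"])
        for s in samples:
            vals = group[s]
            out[s] = np.nan if vals.isna().all() else float(vals.sum(skipna=True))
        out["_order"] = group.index.min()
        return pd.Series(out)

    logger.info("summing %d duplicate peptidoform rows", int(dup.sum()))
    merged = (
        table[dup]
        .groupby(key[dup], sort=False, group_keys=False)
        .apply(_agg)
        .reset_index(drop=True)
    )
    uniques = table[~dup][cols].copy()
    uniques["_order"] = uniques.index
    out = (
        pd.concat([uniques, merged], ignore_index=True)
        .sort_values("_order", kind="mergesort")
        .reset_index(drop=True)
    )
    logger.info("deduplication: %d rows -> %d records", len(table), len(out))
    return out[cols]


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def apply_id_filters(
    table: pd.DataFrame,
    min_score: float | None = 15.0,
    max_fdr: float = 0.01,
    fdr_column: str | None = None,
) -> pd.DataFrame:
    """Apply identification-level filters: peptide score (−10logP) and FDR.

    Defaults mirror standard label-free target–decoy filtering: score ≥ 15
    and 1% FDR. ``min_score=None`` disables the score filter. When the
    score filter is active, rows without a score are removed (their
    identification quality cannot be verified). Idempotent.
    """
    if min_score is not None and min_score < 0:
        raise ValueError(f"min_score must be non-negative, got {min_score}")
    n0 = len(table)
    out = table
    if min_score is not None and "score" in out.columns:
        out = out[out["score"] >= min_score]
    if fdr_column is not None and fdr_column in out.columns:
        out = out[out[fdr_column] <= max_fdr]
    logger.info("id filters: %d rows -> %d", n0, len(out))
    return out.reset_index(drop=True)


def read_gmt(path: str | Path) -> AnnotationSets:
    """Read a GMT gene-set file (term, description, members...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs ≥3 tab-separated fields"
                )
            term, name, *members = fields
            if term in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate term id {term!r}")
            members = frozenset(m for m in members if m)
            if not members:
                raise SchemaError(f"{path}:{lineno}: term {term!r} has no members")
            sets[term] = (name, members)
    return AnnotationSets(sets)


def write_gmt(path: str | Path, sets: AnnotationSets) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sets:
            members = sorted(sets.members(term))
            fh.write("\t".join([term, sets.name(term), *members]) + "\n")
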
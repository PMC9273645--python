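"""Cohort file I/O in a cBioPortal-like tab-delimited dialect.

Matrices are stored gene-per-row with a gene-identifier first column and one
column per patient (the ``data_*.txt`` layout used by cBioPortal study
downloads). Missing cells may be written as ``NA``, ``NaN`` or an empty
string. Clinical and mutation tables are plain one-row-per-record TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_MARKERS = ("NA", "NaN", "nan", "")

CLINICAL_COLUMNS = ["patient_id", "age", "sex", "race", "stage_raw", "os_time", "os_event"]


class FormatError(ValueError):
    """Malformed on-disk file (bad header, wrong delimiter, ragged rows)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a matrix invariant."""


class CohortError(ValueError):
    """Cohort assembly failed (e.g. empty patient intersection)."""


@dataclass
class ExpressionMatrix:
    """Gene x patient expression z-scores; NaN cells are missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique_axes(self.values)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_patients(self, patients) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, patients])


@dataclass
class CnaCallMatrix:
    """Gene x patient GISTIC-style calls in {-2,-1,0,+1,+2}.

    0 is neutral; positive calls are gains/amplifications, negative calls
    deletions; |call| == 2 marks high-level events (amplification or
    homozygous deletion).
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique_axes(self.calls)
        vals = self.calls.to_numpy()
        if vals.size and (np.abs(vals) > 2).any():
            bad = np.argwhere(np.abs(vals) > 2)[0]
            raise ValidationError(
                f"CNA call out of range [-2, 2] at gene "
                f"{self.calls.index[bad[0]]!r}, patient {self.calls.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def patients(self) -> pd.Index:
        return self.calls.columns

    def subset_patients(self, patients) -> "CnaCallMatrix":
        return CnaCallMatrix(self.calls.loc[:, patients])


@dataclass
class Cohort:
    """Aligned multi-omic cohort: expression + CNA calls, optional clinical
    and mutation data, restricted to the shared patient set."""

    expression: ExpressionMatrix
    cna: CnaCallMatrix
    clinical: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None  # gene x patient booleans
    log: list[str] = field(default_factory=list)

    @property
    def patients(self) -> pd.Index:
        return self.expression.patients

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _check_unique_axes(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate patient identifiers: {dupes[:5]}")


def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            dtype=str,
            keep_default_na=False,
            comment="#",
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: cannot parse as tab-delimited matrix: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: header line has no patient columns")
    if df.index.name is None or df.index.name == "":
        raise FormatError(f"{path}: header line lacks a gene-identifier column name")
    return df


def read_matrix(path, kind: str, transposed: bool = False):
    """Read a gene x patient matrix file.

    Parameters
    ----------
    path : path-like
        Tab-delimited file; first column gene ids, remaining columns patients.
    kind : {"expression", "cna"}
        ``expression`` parses real values with a missing mask;
        ``cna`` parses integer calls and rejects values outside [-2, 2].
    transposed : bool
        If True the file is patient-per-row and is transposed on read.
    """
    if kind not in ("expression", "cna"):
        raise ValueError(f"kind must be 'expression' or 'cna', got {kind!r}")
    path = Path(path)
    raw = _read_table(path)
    if transposed:
        raw = raw.T
    raw = raw.replace(list(MISSING_MARKERS), np.nan)

    if kind == "expression":
        try:
            values = raw.astype(float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric expression cell: {exc}") from exc
        if np.isinf(values.to_numpy()).any():
            raise ValidationError(f"{path}: non-finite expression value")
        return ExpressionMatrix(values)

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, p = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric CNA call at gene {raw.index[g]!r}, patient {raw.columns[p]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, p = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing CNA call at gene {raw.index[g]!r}, patient "
            f"{raw.columns[p]!r} (CNA matrix must be complete)"
        )
    arr = numeric.to_numpy()
    if not np.array_equal(arr, np.round(arr)):
        g, p = np.argwhere(arr != np.round(arr))[0]
        raise ValidationError(
            f"{path}: non-integer CNA call at gene {numeric.index[g]!r}, "
            f"patient {numeric.columns[p]!r}"
        )
    return CnaCallMatrix(numeric.astype(np.int8))


def write_matrix(matrix, path) -> None:
    """Write a matrix in the canonical dialect (tab-delimited, NA for missing)."""
    path = Path(path)
    if isinstance(matrix, ExpressionMatrix):
        df = matrix.values
        df.to_csv(path, sep="\t", na_rep="NA", index_label="Hugo_Symbol")
    elif isinstance(matrix, CnaCallMatrix):
        matrix.calls.to_csv(path, sep="\t", index_label="Hugo_Symbol")
    else:
        raise TypeError(f"cannot write object of type {type(matrix).__name__}")


def read_clinical(path) -> pd.DataFrame:
    """Read a per-patient clinical TSV.

    Expected columns: patient_id, age, sex, race, stage_raw, os_time,
    os_event (0/1). Extra columns are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: clinical table lacks columns {missing_cols}")
    df = df.replace(list(MISSING_MARKERS), np.nan)
    if df["patient_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate patient rows in clinical table")
    df = df.set_index("patient_id")
    for col in ("age", "os_time"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="raise").astype(float)
    if (df["os_time"].dropna() < 0).any():
        raise ValidationError(f"{path}: negative overall-survival time")
    if (df["age"].dropna() <= 0).any():
        raise ValidationError(f"{path}: non-positive age")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", na_rep="NA", index_label="patient_id")


def read_mutations(path) -> pd.DataFrame:
    """Read a long-format mutation flag TSV (patient_id, gene, mutated) into
    a gene x patient boolean matrix."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in ("patient_id", "gene", "mutated"):
        if col not in df.columns:
            raise FormatError(f"{path}: mutation table lacks column {col!r}")
    if df.duplicated(subset=["patient_id", "gene"]).any():
        raise ValidationError(f"{path}: duplicate (patient, gene) mutation flags")
    df["mutated"] = df["mutated"].map({"1": True, "0": False, "True": True, "False": False})
    if df["mutated"].isna().any():
        raise ValidationError(f"{path}: mutation flags must be 0/1 or True/False")
    wide = df.pivot(index="gene", columns="patient_id", values="mutated")
    return wide.astype("boolean").fillna(False).astype(bool)


def write_mutations(mutations: pd.DataFrame, path) -> None:
    """Write the gene x patient boolean matrix as a long TSV of True flags."""
    long = mutations.stack()
    long = long[long]
    out = pd.DataFrame(
        {
            "patient_id": long.index.get_level_values(1),
            "gene": long.index.get_level_values(0),
            "mutated": 1,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT gene-set file: one set per line, tab-delimited
    (name, description, member genes...)."""
    sets: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, desc, *genes = parts
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        sets[name] = {"description": desc, "genes": [g for g in genes if g]}
    return sets


def align_cohort(
    expr: ExpressionMatrix,
    cna: CnaCallMatrix,
    clinical: pd.DataFrame | None = None,
    mutations: pd.DataFrame | None = None,
) -> Cohort:
    """Restrict all data types to the patients shared by expression and CNA.

    Patients are put in canonical (sorted) order, so the result is invariant
    to input column permutations. Dropped-patient counts are recorded in the
    cohort's provenance log.
    """
    shared = expr.patients.intersection(cna.patients).sort_values()
    if len(shared) == 0:
        raise CohortError("expression and CNA matrices share no patients")
    log = [
        f"aligned cohort: {len(shared)} patients shared by expression and CNA",
        f"dropped {len(expr.patients) - len(shared)} expression-only patients",
        f"dropped {len(cna.patients) - len(shared)} CNA-only patients",
    ]
    clin = None
    if clinical is not None:
        clin = clinical.loc[clinical.index.intersection(shared).sort_values()]
        log.append(
            f"clinical data present for {len(clin)}/{len(shared)} cohort patients"
        )
    mut = None
    if mutations is not None:
        keep = mutations.columns.intersection(shared).sort_values()
        mut = mutations.loc[:, keep]
        log.append(
            f"mutation data present for {len(keep)}/{len(shared)} cohort patients"
        )
    for line in log:
        logger.info(line)
    return Cohort(
        expression=expr.subset_patients(shared),
        cna=cna.subset_patients(shared),
        clinical=clin,
        mutations=mut,
        log=log,
    )
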
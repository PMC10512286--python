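"""Cohort data model and readers/writers for expression and clinical tables.

A *cohort* joins a normalized gene-expression matrix (genes x samples; any
normalized scale — log2 microarray intensities, variance-stabilized counts,
or z-scores) with a clinical table carrying a right-censored time-to-event
endpoint (e.g. time to biochemical recurrence, or overall survival) plus the
adjustment covariates the downstream Cox models use: chronological age and a
grade measure, which is either a Gleason score (major+minor patterns) for
prostate cohorts or a binary cytogenetic-risk category (favorable vs
unfavorable) for AML cohorts.

Formats are deliberately plain: expression as a tab-separated matrix with a
``gene`` header column, clinical as CSV with a configurable column mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("agingpanel")

GRADE_GLEASON = "gleason"
GRADE_RISK = "risk"

RISK_FAVORABLE = "favorable"
RISK_UNFAVORABLE = "unfavorable"

_GLEASON_RE = re.compile(r"^\s*(\d)\s*\+\s*(\d)\s*$")


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort inputs."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes-in-rows expression matrix with unique gene and sample ids."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CohortError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise CohortError(f"duplicate {kind} identifier: {dupes[0]!r}")
        if not np.all(np.isfinite(self.values)):
            raise CohortError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(sample_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise CohortError(f"unknown sample id(s): {missing[:5]}")
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def rows_for(self, genes: Sequence[str]) -> np.ndarray:
        """Return a (n_samples, len(genes)) matrix of expression values."""
        idx = pd.Index(self.gene_ids).get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise CohortError(f"gene(s) not in expression matrix: {missing}")
        return self.values[idx, :].T.copy()


def read_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (header: gene<TAB>sample ids).

    ``transpose=True`` accepts a samples-in-rows file and transposes on read.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        frame = frame.T
    genes = [str(g) for g in frame.index]
    dup = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dup):
        raise CohortError(f"duplicate gene symbol in {path.name}: {dup[0]!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(frame[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy())[0])
            raise CohortError(
                f"non-numeric expression value at gene {genes[row]!r}, "
                f"sample {col!r} in {path.name}"
            ) from None
    return ExpressionMatrix(genes, [str(s) for s in frame.columns], values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    # default pandas float repr is round-trip exact for float64
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample SD 1 (ddof=1).

    Zero-variance rows are left unscaled and logged, never dropped.
    """
    values = expr.values.copy()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    if flat.any():
        names = [expr.gene_ids[i] for i in np.flatnonzero(flat)]
        logger.warning("zscore_genes: %d zero-variance gene(s) left unscaled: %s",
                       len(names), names[:5])
    sd[flat] = 1.0
    mean[flat] = 0.0
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), (values - mean) / sd)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

#: default CSV column names; override any entry via the ``columns=`` mapping
DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "time": "time",
    "event": "event",
    "age": "age",
    "gleason": "gleason",
    "risk": "risk",
}


@dataclass
class ClinicalTable:
    """Typed clinical records: one row per sample.

    ``data`` columns: sample_id, time (months, > 0), event (0/1), age (years),
    and one grade encoding — gleason_major/gleason_minor integers, or
    risk_category in {favorable, unfavorable}.
    """

    data: pd.DataFrame
    grade_kind: str  # GRADE_GLEASON or GRADE_RISK

    def __post_init__(self) -> None:
        d = self.data
        if self.grade_kind not in (GRADE_GLEASON, GRADE_RISK):
            raise CohortError(f"unknown grade encoding {self.grade_kind!r}")
        required = {"sample_id", "time", "event", "age"}
        required |= ({"gleason_major", "gleason_minor"}
                     if self.grade_kind == GRADE_GLEASON else {"risk_category"})
        missing = required - set(d.columns)
        if missing:
            raise CohortError(f"clinical table missing columns: {sorted(missing)}")
        if len(d) == 0:
            raise CohortError("clinical table has zero usable rows")
        if (d["time"] <= 0).any():
            bad = d.loc[d["time"] <= 0, "sample_id"].iloc[0]
            raise CohortError(f"non-positive follow-up time for sample {bad!r}")
        if not d["event"].isin([0, 1]).all():
            raise CohortError("event flag must be 0 or 1")
        if d["sample_id"].duplicated().any():
            dup = d.loc[d["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CohortError(f"duplicate sample id {dup!r} in clinical table")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data["sample_id"]]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        d = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(d, self.grade_kind)

    def grade_values(self) -> np.ndarray:
        """Numeric grade covariate: Gleason sum (major+minor) or risk 0/1."""
        if self.grade_kind == GRADE_GLEASON:
            return (self.data["gleason_major"] + self.data["gleason_minor"]).to_numpy(float)
        return (self.data["risk_category"] == RISK_UNFAVORABLE).to_numpy(float)


def parse_gleason(text: str) -> tuple[int, int]:
    """Parse a 'major+minor' Gleason string such as '4+3' -> (4, 3)."""
    m = _GLEASON_RE.match(str(text))
    if not m:
        raise CohortError(f"cannot parse Gleason score {text!r} (expected 'a+b')")
    major, minor = int(m.group(1)), int(m.group(2))
    if not (3 <= major <= 5 and 3 <= minor <= 5):
        raise CohortError(f"Gleason patterns out of range in {text!r}")
    return major, minor


def read_clinical(
    path: str | Path,
    grade_kind: str,
    columns: Mapping[str, str] | None = None,
) -> ClinicalTable:
    """Read a clinical CSV with a declared column mapping.

    Rows missing time, event, age, or the grade field are dropped listwise,
    with the count logged. Negative/zero time or zero usable rows are errors.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    grade_col = cols["gleason"] if grade_kind == GRADE_GLEASON else cols["risk"]
    for key in ("sample_id", "time", "event", "age"):
        if cols[key] not in raw.columns:
            raise CohortError(f"{path.name}: missing column {cols[key]!r}")
    if grade_col not in raw.columns:
        raise CohortError(f"{path.name}: missing grade column {grade_col!r}")

    out = pd.DataFrame({
        "sample_id": raw[cols["sample_id"]].astype(str),
        "time": pd.to_numeric(raw[cols["time"]], errors="coerce"),
        "event": pd.to_numeric(raw[cols["event"]], errors="coerce"),
        "age": pd.to_numeric(raw[cols["age"]], errors="coerce"),
    })
    grade_raw = raw[grade_col]
    if grade_kind == GRADE_GLEASON:
        majors, minors = [], []
        for g in grade_raw:
            if pd.isna(g) or str(g).strip() == "":
                majors.append(np.nan)
                minors.append(np.nan)
            else:
                a, b = parse_gleason(g)
                majors.append(a)
                minors.append(b)
        out["gleason_major"] = majors
        out["gleason_minor"] = minors
        grade_missing = out["gleason_major"].isna()
    else:
        cat = grade_raw.astype(str).str.strip().str.lower()
        cat = cat.where(cat.isin([RISK_FAVORABLE, RISK_UNFAVORABLE]))
        out["risk_category"] = cat
        grade_missing = cat.isna()

    usable = ~(out[["time", "event", "age"]].isna().any(axis=1) | grade_missing)
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("read_clinical(%s): dropped %d row(s) with missing fields",
                    path.name, n_drop)
    out = out.loc[usable].reset_index(drop=True)
    if len(out) == 0:
        raise CohortError(f"{path.name}: zero usable clinical rows")
    if (out["time"] <= 0).any():
        bad = out.loc[out["time"] <= 0, "sample_id"].iloc[0]
        raise CohortError(f"{path.name}: non-positive time for sample {bad!r}")
    if grade_kind == GRADE_GLEASON:
        out["gleason_major"] = out["gleason_major"].astype(int)
        out["gleason_minor"] = out["gleason_minor"].astype(int)
    out["event"] = out["event"].astype(int)
    return ClinicalTable(out, grade_kind)


def write_clinical(clin: ClinicalTable, path: str | Path,
                   columns: Mapping[str, str] | None = None) -> None:
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    d = clin.data
    out = pd.DataFrame({
        cols["sample_id"]: d["sample_id"],
        cols["time"]: d["time"],
        cols["event"]: d["event"],
        cols["age"]: d["age"],
    })
    if clin.grade_kind == GRADE_GLEASON:
        out[cols["gleason"]] = [f"{a}+{b}" for a, b in
                                zip(d["gleason_major"], d["gleason_minor"])]
    else:
        out[cols["risk"]] = d["risk_category"]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Joined expression + clinical data for one study."""

    name: str
    expression: ExpressionMatrix
    clinical: ClinicalTable
    endpoint_label: str = "time-to-event"

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise CohortError(
                f"cohort {self.name!r}: expression and clinical sample sets differ"
            )
        if int(self.clinical.data["event"].sum()) == 0:
            raise CohortError(f"cohort {self.name!r}: no events present")

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def time(self) -> np.ndarray:
        return self.clinical.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical.data["event"].to_numpy(int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Columns for adjustment covariates: 'age' (years) and/or 'grade'."""
        cols = []
        for name in names:
            if name == "age":
                cols.append(self.clinical.data["age"].to_numpy(float))
            elif name == "grade":
                cols.append(self.clinical.grade_values())
            else:
                raise CohortError(f"unknown adjustment covariate {name!r}")
        if not cols:
            return np.empty((self.n_samples, 0))
        return np.column_stack(cols)

    def subset(self, sample_ids: Sequence[str], name: str | None = None) -> "Cohort":
        return Cohort(
            name=name or self.name,
            expression=self.expression.subset_samples(sample_ids),
            clinical=self.clinical.subset(sample_ids),
            endpoint_label=self.endpoint_label,
        )


def assemble_cohort(expr: ExpressionMatrix, clin: ClinicalTable, name: str,
                    endpoint_label: str = "time-to-event") -> Cohort:
    """Inner-join expression and clinical on sample id (sorted, deterministic)."""
    shared = sorted(set(expr.sample_ids) & set(clin.sample_ids))
    if not shared:
        raise CohortError(f"cohort {name!r}: no shared sample ids between "
                          "expression and clinical tables")
    dropped = (len(expr.sample_ids) - len(shared), len(clin.sample_ids) - len(shared))
    if any(dropped):
        logger.info("assemble_cohort(%s): dropped %d expression-only and %d "
                    "clinical-only sample(s)", name, *dropped)
    cohort = Cohort(name, expr.subset_samples(shared), clin.subset(shared),
                    endpoint_label)
    return cohort
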
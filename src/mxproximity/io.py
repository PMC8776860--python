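"""Tabular ingest and export.

Three table families feed the pipeline:

* per-slide cell-centroid tables (one row per segmented cell: coordinates in
  micrometres, binary marker calls from a declared panel, nucleated flag) —
  the contract for upstream single-cell segmentation output;
* a clinical table linking each patient's pre-treatment and at-progression
  slides to progression-free survival;
* a cohort table in the cBioPortal export dialect (tab-separated clinical
  file plus genes x samples expression matrix) for the survival stage.

All writers emit UTF-8, LF line endings and a deterministic column order so
that write/read round-trips are byte-stable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import FormatError, LinkageError, ValidationError

logger = logging.getLogger(__name__)

#: Marker panel used throughout the melanoma analysis: tumor lineage (SOX10),
#: cytotoxic T cells (CD8), dendritic cells (CD11c) and the costimulatory
#: molecules CD40 / CD80.
DEFAULT_PANEL: tuple[str, ...] = ("SOX10", "CD8", "CD11c", "CD40", "CD80")

_CELL_REQUIRED = ("slide_id", "cell_id", "x_um", "y_um", "nucleated")
_CLINICAL_REQUIRED = (
    "patient_id",
    "pre_slide_id",
    "post_slide_id",
    "pfs_months",
    "progression_event",
)


@dataclass
class SlideCellTable:
    """Cell centroids and binary marker calls for a single slide.

    ``cells`` holds one row per cell with columns ``cell_id``, ``x_um``,
    ``y_um``, ``nucleated`` and one boolean column per panel marker.
    Coordinates are centroid positions in micrometres, origin at the slide's
    top-left corner, y increasing downward.

    ``region_area_mm2`` is the tissue area used as the density denominator.
    When absent it is computed lazily as the axis-aligned bounding box of all
    nucleated cells (logged, since slides rarely ship a tissue mask).
    """

    slide_id: str
    cells: pd.DataFrame
    panel: tuple[str, ...] = DEFAULT_PANEL
    region_area_mm2: float | None = None

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        self.validate()

    def validate(self) -> None:
        cols = set(self.cells.columns)
        for c in ("cell_id", "x_um", "y_um", "nucleated"):
            if c not in cols:
                raise FormatError(f"cell table missing required column {c!r}")
        for m in self.panel:
            if m not in cols:
                raise FormatError(f"cell table missing panel marker column {m!r}")
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate cell_id {dup!r} on slide {self.slide_id!r}"
            )
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError(f"non-finite coordinate on slide {self.slide_id!r}")
        if (xy < 0).any():
            raise ValidationError(f"negative coordinate on slide {self.slide_id!r}")
        if self.region_area_mm2 is not None and not self.region_area_mm2 > 0:
            raise ValidationError("region_area_mm2 must be > 0")

    # -- derived quantities -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def area_mm2(self) -> float:
        """Density denominator; falls back to the nucleated bounding box."""
        if self.region_area_mm2 is not None:
            return float(self.region_area_mm2)
        nuc = self.cells[self.cells["nucleated"].astype(bool)]
        if len(nuc) < 2:
            raise ValidationError(
                f"slide {self.slide_id!r}: cannot derive an area from "
                f"{len(nuc)} nucleated cells and no region_area_mm2"
            )
        w = float(nuc["x_um"].max() - nuc["x_um"].min())
        h = float(nuc["y_um"].max() - nuc["y_um"].min())
        area = w * h / 1e6
        if area <= 0:
            raise ValidationError(
                f"slide {self.slide_id!r}: degenerate bounding box, supply "
                "region_area_mm2 explicitly"
            )
        logger.warning(
            "slide %s: region_area_mm2 absent, using nucleated bounding box "
            "(%.4f mm2)", self.slide_id, area,
        )
        return area

    def marker_mask(self, marker: str) -> np.ndarray:
        if marker not in self.panel:
            raise ValidationError(
                f"marker {marker!r} not in panel {self.panel}"
            )
        return self.cells[marker].to_numpy(dtype=bool)

    def marker_count(self, marker: str) -> int:
        return int(self.marker_mask(marker).sum())

    def positions(self, marker: str | None = None) -> np.ndarray:
        """(n, 2) centroid array, optionally restricted to one marker."""
        df = self.cells
        if marker is not None:
            df = df[self.marker_mask(marker)]
        return df[["x_um", "y_um"]].to_numpy(dtype=float)

    def with_area(self, area_mm2: float) -> "SlideCellTable":
        return replace(self, region_area_mm2=area_mm2)


@dataclass(frozen=True)
class PatientPairRecord:
    """Linkage of one patient's pre-treatment and at-progression slides."""

    patient_id: str
    pre_slide_id: str
    post_slide_id: str
    pfs_months: float
    progression_event: bool
    prior_immunotherapy: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.pfs_months) or self.pfs_months < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: pfs_months must be finite and "
                f">= 0, got {self.pfs_months}"
            )
        if self.pre_slide_id == self.post_slide_id:
            raise ValidationError(
                f"patient {self.patient_id!r}: pre and post slide ids must differ"
            )


#: Columns every cohort table carries; gene expression columns are prefixed
#: ``expr_`` and enumerated in :attr:`CohortTable.gene_columns`.
_COHORT_REQUIRED = (
    "patient_id",
    "os_months",
    "os_event",
    "stage_group",
    "sex",
    "immune_score",
    "sox10_z",
    "mlana_z",
    "cd8a_expr",
)


@dataclass
class CohortTable:
    """Per-patient survival outcomes and expression covariates.

    ``df`` has one row per patient with the columns in ``_COHORT_REQUIRED``
    plus one ``expr_<GENE>`` column per downstream response gene. Stage is
    pre-mapped to ``early`` (I/II), ``late`` (III/IV) or ``excluded``.
    """

    df: pd.DataFrame
    gene_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.gene_columns = tuple(self.gene_columns)
        missing = [c for c in _COHORT_REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"cohort table missing columns {missing}")
        bad = set(self.df["stage_group"].dropna()) - {"early", "late", "excluded"}
        if bad:
            raise ValidationError(f"undefined stage_group values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# stage mapping (cBioPortal AJCC stage strings)
# ---------------------------------------------------------------------------

def map_stage(stage: object) -> str:
    """Map an AJCC stage string to ``early`` / ``late`` / ``excluded``.

    Sub-stages IA..IIC and bare I/II are early; IIIA..IV are late. Stage 0,
    "I/II NOS" and anything unparseable map to ``excluded`` (total mapping:
    every input lands in exactly one bucket).
    """
    if stage is None or (isinstance(stage, float) and math.isnan(stage)):
        return "excluded"
    s = str(stage).strip().upper()
    s = s.removeprefix("STAGE").strip()
    if s in {"0", "IS"}:
        return "excluded"
    if "NOS" in s:
        return "excluded"
    core = s.rstrip("ABC")
    if core in {"I", "II"}:
        return "early"
    if core in {"III", "IV"}:
        return "late"
    logger.warning("unparseable stage string %r mapped to excluded", stage)
    return "excluded"


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    for c in required:
        if c not in df.columns:
            raise FormatError(f"{what} is missing required column {c!r}")


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based numbering
        line = int(bad.idxmax()) + 2
        raise FormatError(
            f"{what}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"{col!r} at line {line}"
        )
    return out


def read_cell_tables(
    path,
    panel: tuple[str, ...] = DEFAULT_PANEL,
    microns_per_pixel: float = 1.0,
) -> dict[str, SlideCellTable]:
    """Read a centroid CSV possibly covering several slides.

    Marker columns must be 0/1; coordinates are multiplied by
    ``microns_per_pixel`` (default 1.0, i.e. already in micrometres).
    Unknown columns are ignored with a logged warning.
    """
    df = pd.read_csv(path, dtype={"slide_id": str, "cell_id": str})
    _require_columns(df, _CELL_REQUIRED, f"cell table {path}")
    known = set(_CELL_REQUIRED) | set(panel)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("cell table %s: ignoring unknown columns %s", path, extra)
    for m in panel:
        if m not in df.columns:
            raise FormatError(f"cell table {path} is missing marker column {m!r}")

    out: dict[str, SlideCellTable] = {}
    for slide_id, grp in df.groupby("slide_id", sort=True):
        cells = pd.DataFrame({
            "cell_id": grp["cell_id"].astype(str).to_numpy(),
            "x_um": _numeric(grp, "x_um", f"slide {slide_id}").to_numpy()
            * microns_per_pixel,
            "y_um": _numeric(grp, "y_um", f"slide {slide_id}").to_numpy()
            * microns_per_pixel,
            "nucleated": _binary(grp, "nucleated", slide_id),
        })
        for m in panel:
            cells[m] = _binary(grp, m, slide_id)
        cells = cells.reset_index(drop=True)
        out[str(slide_id)] = SlideCellTable(str(slide_id), cells, panel)
    return out


def _binary(df: pd.DataFrame, col: str, slide_id) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    ok = vals.isin([0, 1]) | vals.isna()
    if vals.isna().any() or not ok.all():
        raise FormatError(
            f"slide {slide_id}: column {col!r} must be 0/1"
        )
    return vals.to_numpy(dtype=bool)


def read_cell_table(
    path,
    panel: tuple[str, ...] = DEFAULT_PANEL,
    microns_per_pixel: float = 1.0,
) -> SlideCellTable:
    """Read a centroid CSV that covers exactly one slide."""
    tables = read_cell_tables(path, panel, microns_per_pixel)
    if len(tables) != 1:
        raise FormatError(
            f"cell table {path} contains {len(tables)} slide ids; expected 1"
        )
    return next(iter(tables.values()))


def write_cell_tables(tables, path) -> None:
    """Write one or more slides to CSV in canonical column order."""
    if isinstance(tables, SlideCellTable):
        tables = [tables]
    elif isinstance(tables, dict):
        tables = [tables[k] for k in sorted(tables)]
    frames = []
    for t in tables:
        df = t.cells.copy()
        df.insert(0, "slide_id", t.slide_id)
        for c in ("nucleated", *t.panel):
            df[c] = df[c].astype(int)
        frames.append(df[["slide_id", "cell_id", "x_um", "y_um", "nucleated",
                          *t.panel]])
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, lineterminator="\n", float_format="%.6f"
    )


# ---------------------------------------------------------------------------
# clinical pre/post linkage table
# ---------------------------------------------------------------------------

def read_clinical_table(path) -> list[PatientPairRecord]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _CLINICAL_REQUIRED, f"clinical table {path}")
    records = []
    for _, row in df.iterrows():
        records.append(PatientPairRecord(
            patient_id=str(row["patient_id"]),
            pre_slide_id=str(row["pre_slide_id"]),
            post_slide_id=str(row["post_slide_id"]),
            pfs_months=float(row["pfs_months"]),
            progression_event=_parse_bool(row["progression_event"]),
            prior_immunotherapy=_parse_bool(row.get("prior_immunotherapy", "0")),
        ))
    return records


def _parse_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no"}:
        return False
    raise FormatError(f"cannot parse boolean value {v!r}")


def write_clinical_table(records, path) -> None:
    df = pd.DataFrame([{
        "patient_id": r.patient_id,
        "pre_slide_id": r.pre_slide_id,
        "post_slide_id": r.post_slide_id,
        "pfs_months": r.pfs_months,
        "progression_event": int(r.progression_event),
        "prior_immunotherapy": int(r.prior_immunotherapy),
    } for r in records])
    df.to_csv(path, index=False, lineterminator="\n")


def link_cohort(slides: dict[str, SlideCellTable], clinical) -> None:
    """Check every clinical slide id resolves; raise LinkageError otherwise."""
    missing = [
        r.patient_id for r in clinical
        if r.pre_slide_id not in slides or r.post_slide_id not in slides
    ]
    if missing:
        raise LinkageError(
            f"unresolved slide ids for patients: {sorted(missing)}"
        )


# ---------------------------------------------------------------------------
# cBioPortal-dialect cohort ingest
# ---------------------------------------------------------------------------

def read_tcga_cohort(
    clinical_path,
    expression_path,
    *,
    expression_is_zscore: bool = False,
    marker_genes: tuple[str, str] = ("SOX10", "MLANA"),
    cd8_gene: str = "CD8A",
    response_genes: tuple[str, ...] = ("PDCD1", "CD274", "IFNG", "GZMB"),
) -> CohortTable:
    """Join a cBioPortal-style clinical TSV with an expression matrix.

    The clinical file is tab-separated with '#'-comment lines skipped and
    columns PATIENT_ID, OS_MONTHS, OS_STATUS, AJCC stage and SEX (an optional
    IMMUNE_SCORE column carries a precomputed immune-infiltration score).
    The expression matrix is genes x samples with the gene symbol in the
    first column. When the matrix holds raw expression, marker z-scores are
    computed per gene over the joined samples; when it already holds
    z-scores set ``expression_is_zscore=True`` to pass them through.
    """
    clin = pd.read_csv(clinical_path, sep="\t", comment="#", dtype=str)
    clin.columns = [c.strip().upper() for c in clin.columns]
    _require_columns(clin, ("PATIENT_ID", "OS_MONTHS", "OS_STATUS"),
                     f"clinical file {clinical_path}")
    stage_col = next(
        (c for c in clin.columns if "STAGE" in c), None)
    if stage_col is None:
        raise FormatError(f"clinical file {clinical_path} has no stage column")

    expr = pd.read_csv(expression_path, sep="\t", comment="#")
    gene_col = expr.columns[0]
    expr = expr.set_index(gene_col)
    for g in (*marker_genes, cd8_gene):
        if g not in expr.index:
            raise FormatError(
                f"expression matrix {expression_path} is missing gene {g!r}"
            )

    samples = [c for c in expr.columns if c in set(clin["PATIENT_ID"])]
    n_clin_only = clin["PATIENT_ID"].nunique() - len(samples)
    n_expr_only = len(expr.columns) - len(samples)
    if not samples:
        raise LinkageError(
            f"no shared sample ids: {clin['PATIENT_ID'].nunique()} clinical "
            f"vs {len(expr.columns)} expression columns"
        )
    if n_clin_only or n_expr_only:
        logger.warning(
            "sample join dropped %d clinical-only and %d expression-only ids",
            n_clin_only, n_expr_only,
        )

    clin = clin.set_index("PATIENT_ID").loc[samples]
    sub = expr[samples].apply(pd.to_numeric, errors="coerce")

    def zrow(gene: str) -> np.ndarray:
        x = sub.loc[gene].to_numpy(dtype=float)
        if expression_is_zscore:
            return x
        sd = float(np.std(x, ddof=1))
        if not sd > 0:
            raise ValidationError(f"gene {gene!r} is constant; z-score undefined")
        return (x - float(np.mean(x))) / sd

    os_months = pd.to_numeric(clin["OS_MONTHS"], errors="coerce")
    os_event = clin["OS_STATUS"].map(
        lambda s: np.nan if pd.isna(s) else float("DECEASED" in str(s).upper())
    )
    immune = (
        pd.to_numeric(clin["IMMUNE_SCORE"], errors="coerce")
        if "IMMUNE_SCORE" in clin.columns
        else pd.Series(np.nan, index=clin.index)
    )

    df = pd.DataFrame({
        "patient_id": samples,
        "os_months": os_months.to_numpy(),
        "os_event": os_event.to_numpy(),
        "stage_group": [map_stage(s) for s in clin[stage_col]],
        "sex": clin.get("SEX", pd.Series("", index=clin.index)).fillna("").to_numpy(),
        "immune_score": immune.to_numpy(),
        "sox10_z": zrow(marker_genes[0]),
        "mlana_z": zrow(marker_genes[1]),
        "cd8a_expr": sub.loc[cd8_gene].to_numpy(dtype=float),
    })
    gene_cols = []
    for g in response_genes:
        if g in sub.index:
            col = f"expr_{g}"
            df[col] = sub.loc[g].to_numpy(dtype=float)
            gene_cols.append(col)
    return CohortTable(df.reset_index(drop=True), tuple(gene_cols))


def write_cohort_table(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_cohort_table(path) -> CohortTable:
    """Read a cohort TSV previously written by :func:`write_cohort_table`."""
    df = pd.read_csv(path, sep="\t")
    genes = tuple(c for c in df.columns if c.startswith("expr_"))
    return CohortTable(df, genes)
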
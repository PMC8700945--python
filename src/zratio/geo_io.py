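"""Reading and writing GEO-style series-matrix files and sample metadata.

A series-matrix file is a plain-text, tab-separated table of log2 probe
intensities bracketed by ``!series_matrix_table_begin`` and
``!series_matrix_table_end`` markers, preceded by ``!Sample_...`` header
lines that carry per-sample metadata as free-text ``key: value``
characteristics.  Because GEO characteristics lines are free text, the
patterns that extract karyotype group, brain region, age and sex are
configurable regexes; the defaults match the vocabulary used by brain
trisomy-21 expression series.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"

#: The 11 brain-region codes used for stratified analysis.
REGIONS = ("HIP", "CBC", "DFC", "OFC", "VFC", "MFC", "S1C", "IPC", "V1C", "STC", "ITC")
UNKNOWN = "unknown"

#: Default regexes mapping characteristics keys to metadata fields.
DEFAULT_KEY_PATTERNS: dict[str, str] = {
    "group": r"(?:karyotype|group|disease(?:.?state)?|condition)",
    "region": r"(?:brain.?region|region|brain.?area|area|tissue)",
    "age": r"age",
    "sex": r"(?:sex|gender)",
}

#: Values (lower-cased) recognized as the trisomic / control groups.
GROUP_ALIASES = {
    "ds": "DS",
    "down syndrome": "DS",
    "trisomy 21": "DS",
    "t21": "DS",
    "control": "control",
    "ctl": "control",
    "euploid": "control",
    "ctrl": "control",
}

_AGE_RE = re.compile(r"([0-9]+(?:\.[0-9]+)?)\s*(WG|PCW|M|MO|MONTHS?|Y|YRS?|YEARS?)\b", re.I)
_AGE_UNIT_CANON = {
    "WG": "WG", "PCW": "WG",
    "M": "M", "MO": "M", "MONTH": "M", "MONTHS": "M",
    "Y": "Y", "YR": "Y", "YRS": "Y", "YEAR": "Y", "YEARS": "Y",
}


class SeriesMatrixParseError(ValueError):
    """Raised when a series-matrix file cannot be parsed."""


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation: karyotype group, brain region, age, sex."""

    sample_id: str
    group: str  # "DS" | "control"
    region: str = UNKNOWN
    age_value: float | None = None
    age_unit: str | None = None  # "WG" | "M" | "Y"
    sex: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.group not in ("DS", "control"):
            raise ValueError(f"group must be 'DS' or 'control', got {self.group!r}")
        if self.region not in REGIONS and self.region != UNKNOWN:
            raise ValueError(f"unknown region code {self.region!r} for sample {self.sample_id}")
        if self.age_unit is not None:
            if self.age_unit not in ("WG", "M", "Y"):
                raise ValueError(f"age_unit must be WG/M/Y, got {self.age_unit!r}")
            if self.age_value is None or self.age_value <= 0:
                raise ValueError(
                    f"age_value must be > 0 when age_unit is given (sample {self.sample_id})"
                )
        if self.sex not in ("F", "M", UNKNOWN):
            raise ValueError(f"sex must be F/M/unknown, got {self.sex!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with its Entrez identifier and cytoband locus."""

    gene_symbol: str
    entrez_id: int
    locus: str


@dataclass
class ExpressionMatrix:
    """Probe (or gene) by sample matrix of expression intensities.

    ``values`` is a DataFrame with probe/gene identifiers on the index and
    sample identifiers on the columns.  ``scale_tag`` records whether the
    stored numbers are log2 intensities or linear-scale intensities.
    """

    values: pd.DataFrame
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "linear"):
            raise ValueError(f"scale_tag must be 'log2' or 'linear', got {self.scale_tag!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_join(self, metadata: Sequence[SampleMetadata]) -> None:
        """Raise if any metadata sample is absent from the matrix.

        A missing sample column must never be silently dropped: a
        metadata/matrix mismatch is a data-integrity failure.
        """
        missing = [m.sample_id for m in metadata if m.sample_id not in self.values.columns]
        if missing:
            raise KeyError(f"metadata samples absent from matrix: {missing}")


def _extract_metadata(
    sample_ids: Sequence[str],
    characteristics: Mapping[str, list[str]],
    key_patterns: Mapping[str, str],
) -> list[SampleMetadata]:
    pats = {k: re.compile(v, re.I) for k, v in key_patterns.items()}
    records = []
    for sid in sample_ids:
        fields: dict[str, object] = {"sample_id": sid}
        for chunk in characteristics.get(sid, []):
            if ":" not in chunk:
                continue
            key, _, value = chunk.partition(":")
            key, value = key.strip(), value.strip()
            if pats["group"].search(key):
                canon = GROUP_ALIASES.get(value.lower())
                if canon is None:
                    raise SeriesMatrixParseError(
                        f"unrecognized group value {value!r} for sample {sid}"
                    )
                fields["group"] = canon
            elif pats["region"].search(key):
                fields["region"] = value.upper() if value.upper() in REGIONS else UNKNOWN
            elif pats["age"].search(key):
                m = _AGE_RE.search(value)
                if m:
                    fields["age_value"] = float(m.group(1))
                    fields["age_unit"] = _AGE_UNIT_CANON[m.group(2).upper()]
            elif pats["sex"].search(key):
                v = value.upper()[:1]
                fields["sex"] = v if v in ("F", "M") else UNKNOWN
        if "group" not in fields:
            raise SeriesMatrixParseError(f"no group/karyotype characteristic for sample {sid}")
        records.append(SampleMetadata(**fields))  # type: ignore[arg-type]
    return records


def parse_series_matrix(
    path: str | Path,
    key_patterns: Mapping[str, str] | None = None,
    scale_tag: str = "log2",
) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Parse a series-matrix text file into a matrix and metadata records.

    Parameters
    ----------
    path
        Series-matrix file with ``!series_matrix_table_begin/end`` markers.
    key_patterns
        Regexes (by field: group/region/age/sex) matching the keys of the
        ``!Sample_characteristics_ch1`` lines; defaults handle the common
        GEO vocabulary.
    scale_tag
        Scale of the stored values; the deposited data this reader targets
        are log2-transformed, so the default is ``"log2"``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        begin = next(i for i, ln in enumerate(lines) if ln.strip().lower() == TABLE_BEGIN)
        end = next(i for i, ln in enumerate(lines) if ln.strip().lower() == TABLE_END)
    except StopIteration:
        raise SeriesMatrixParseError(f"{path}: missing series-matrix table markers") from None
    if end <= begin + 1:
        raise SeriesMatrixParseError(f"{path}: empty series-matrix table")

    characteristics: dict[str, list[str]] = {}
    header_sample_ids: list[str] = []
    for ln in lines[:begin]:
        if not ln.startswith("!Sample_"):
            continue
        parts = [p.strip().strip('"') for p in ln.split("\t")]
        tag = parts[0]
        if tag == "!Sample_geo_accession":
            header_sample_ids = parts[1:]
            for sid in header_sample_ids:
                characteristics.setdefault(sid, [])
        elif tag.startswith("!Sample_characteristics") and header_sample_ids:
            for sid, chunk in zip(header_sample_ids, parts[1:]):
                characteristics[sid].append(chunk)

    table_lines = lines[begin + 1 : end]
    if len(table_lines) < 2:
        raise SeriesMatrixParseError(f"{path}: series-matrix table has zero data rows")
    header_cols = [c.strip().strip('"') for c in table_lines[0].split("\t")[1:]]
    dup_cols = pd.Index(header_cols)
    if dup_cols.duplicated().any():
        raise SeriesMatrixParseError(
            f"{path}: duplicate sample id(s): {dup_cols[dup_cols.duplicated()].unique().tolist()}"
        )
    df = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0, dtype=str)
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index = [str(i).strip('"') for i in df.index]
    if df.shape[0] == 0:
        raise SeriesMatrixParseError(f"{path}: series-matrix table has zero data rows")
    if len(set(df.columns)) != len(df.columns):
        dups = pd.Index(df.columns)
        raise SeriesMatrixParseError(
            f"{path}: duplicate sample id(s): {dups[dups.duplicated()].unique().tolist()}"
        )

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.values.argmax()]
            raise SeriesMatrixParseError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        numeric[col] = converted
    matrix = ExpressionMatrix(numeric, scale_tag=scale_tag)

    sample_ids = header_sample_ids or list(df.columns)
    metadata = _extract_metadata(
        sample_ids, characteristics, {**DEFAULT_KEY_PATTERNS, **(key_patterns or {})}
    )
    matrix.check_join(metadata)
    return matrix, metadata


def write_series_matrix(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    path: str | Path,
) -> None:
    """Write a matrix and metadata to a re-parseable series-matrix file.

    Values are written with 10 significant digits, so a write/parse
    round-trip preserves them well within 1e-5.
    """
    if matrix.values.shape[0] == 0 or matrix.values.shape[1] == 0:
        raise ValueError("refusing to write an empty expression matrix")
    matrix.check_join(metadata)
    if {m.sample_id for m in metadata} != set(matrix.sample_ids):
        raise ValueError("metadata sample set does not match matrix columns")
    meta_by_id = {m.sample_id: m for m in metadata}
    ordered = [meta_by_id[s] for s in matrix.sample_ids]

    def char_line(key: str, values: Iterable[str]) -> str:
        return "\t".join([f"!Sample_characteristics_ch1"] + [f'"{key}: {v}"' for v in values])

    with open(path, "w") as fh:
        fh.write("!Series_title\t\"synthetic series\"\n")
        fh.write("\t".join(["!Sample_geo_accession"] + [f'"{s}"' for s in matrix.sample_ids]) + "\n")
        fh.write(char_line("group", (m.group for m in ordered)) + "\n")
        fh.write(char_line("brain region", (m.region for m in ordered)) + "\n")
        fh.write(
            char_line(
                "age",
                (
                    f"{m.age_value:.10g} {m.age_unit}" if m.age_unit else "unknown"
                    for m in ordered
                ),
            )
            + "\n"
        )
        fh.write(char_line("sex", (m.sex for m in ordered)) + "\n")
        fh.write(TABLE_BEGIN + "\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in matrix.sample_ids]) + "\n")
        for probe, row in matrix.values.iterrows():
            fh.write("\t".join([f'"{probe}"'] + [f"{v:.10g}" for v in row]) + "\n")
        fh.write(TABLE_END + "\n")


def map_probes_to_genes(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    collapse: str = "mean",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    ``annotation`` needs columns ``probe_id`` and ``gene_symbol``; probes
    without a mapping are dropped (their count is logged).  When several
    probes map to one gene their values are combined per sample by the
    ``collapse`` rule (mean, median or max).
    """
    if annotation.empty:
        raise ValueError("empty probe annotation")
    if collapse not in ("mean", "median", "max"):
        raise ValueError(f"collapse must be mean/median/max, got {collapse!r}")
    ann = annotation.drop_duplicates(subset="probe_id").set_index("probe_id")["gene_symbol"]
    mapped = matrix.values.index.intersection(ann.index)
    n_dropped = matrix.values.shape[0] - len(mapped)
    if n_dropped:
        logger.info("map_probes_to_genes: dropped %d unmapped probe(s)", n_dropped)
    sub = matrix.values.loc[mapped]
    collapsed = sub.groupby(ann.loc[mapped].values).agg(collapse)
    collapsed.index.name = "gene_symbol"
    return ExpressionMatrix(collapsed, scale_tag=matrix.scale_tag)


# --- TSV side formats -------------------------------------------------------

_META_COLUMNS = ["sample_id", "group", "region", "age_value", "age_unit", "sex"]


def read_metadata_tsv(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata from a TSV with the standard six columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        has_age = pd.notna(row["age_unit"]) and str(row["age_unit"]).strip() != ""
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                group=row["group"],
                region=row["region"] if pd.notna(row["region"]) else UNKNOWN,
                age_value=float(row["age_value"]) if has_age else None,
                age_unit=str(row["age_unit"]) if has_age else None,
                sex=row["sex"] if pd.notna(row["sex"]) else UNKNOWN,
            )
        )
    return records


def write_metadata_tsv(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "group": m.group,
            "region": m.region,
            "age_value": "" if m.age_value is None else f"{m.age_value:.10g}",
            "age_unit": m.age_unit or "",
            "sex": m.sex,
        }
        for m in metadata
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, gene_symbol[, entrez_id])."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise ValueError(f"annotation TSV missing column {col!r}")
    return df


def load_hmgn_annotation() -> list[GeneAnnotation]:
    """Load the bundled annotation of the five human HMGN genes.

    HMGN1–5 encode the high-mobility-group nucleosome-binding proteins;
    HMGN1 lies on 21q22.2 and is therefore present in three copies in
    trisomy 21.
    """
    text = resources.files("zratio.data").joinpath("hmgn_annotation.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    recs = [
        GeneAnnotation(r.gene_symbol, int(r.entrez_id), r.locus) for r in df.itertuples()
    ]
    if len({r.entrez_id for r in recs}) != len(recs):
        raise ValueError("duplicate entrez ids in bundled annotation")
    return recs
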
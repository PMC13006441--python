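"""Read and write the TSV/CSV artifacts consumed by the pipeline.

Matrix orientation is samples-in-rows.  Delimiter auto-detection is limited
to tab and comma; an explicit ``dialect`` overrides it.  Missing-value
tokens are "", "NA" and "NaN".  An optional reader for the vendor ".adat"
container is a documented extension point, not implemented.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from serumscape.types import (
    MASK_MISSING,
    MASK_OBSERVED,
    AptamerAnnotation,
    IntensityMatrix,
    SampleMetadata,
    SecretomeFunction,
    SecretomeLocation,
    SubcellularClass,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA", "NaN")


def _detect_delimiter(path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect in ("\t", "tab", "tsv"):
            return "\t"
        if dialect in (",", "comma", "csv"):
            return ","
        raise ValueError(f"unsupported dialect {dialect!r}; use 'tab' or 'comma'")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_intensity_matrix(path, dialect: Optional[str] = None) -> IntensityMatrix:
    """Load a samples x aptamers intensity table.

    First column holds sample ids, header row aptamer ids.  Non-numeric
    cells become missing; duplicate ids or non-positive observed values are
    hard errors.
    """
    path = Path(path)
    sep = _detect_delimiter(path, dialect)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate aptamer ids in {path}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str,
        na_values=list(MISSING_TOKENS), keep_default_na=False,
    )
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    values = df.apply(pd.to_numeric, errors="coerce")
    vals = values.to_numpy(dtype=float)
    observed = np.isfinite(vals)
    bad = observed & ~(vals > 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive observed intensity in {path} at sample "
            f"{values.index[i]!r}, aptamer {values.columns[j]!r}: {vals[i, j]!r}"
        )
    mask = pd.DataFrame(
        np.where(observed, MASK_OBSERVED, MASK_MISSING),
        index=values.index, columns=values.columns, dtype=np.int8,
    )
    return IntensityMatrix(values, mask)


def write_intensity_matrix(matrix: IntensityMatrix, path, mask_path=None) -> None:
    """Write an intensity matrix as TSV; mask optionally to a companion TSV."""
    matrix.values.to_csv(path, sep="\t", index_label="sample_id")
    if mask_path is not None:
        matrix.mask.to_csv(mask_path, sep="\t", index_label="sample_id")


def load_mask(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(np.int8)


def _enum_or_fallback(token, enum_cls, fallback, counter: dict) -> object:
    token = (token or "").strip()
    if token == "":
        return fallback
    for member in enum_cls:
        if member.value == token:
            return member
    counter["n"] += 1
    return fallback


def _parse_set(token) -> frozenset:
    token = (token or "").strip()
    if not token:
        return frozenset()
    return frozenset(t for t in token.split(";") if t)


def _parse_bool(token) -> bool:
    return str(token).strip().lower() in ("1", "true", "yes")


def load_annotations(path, dialect: Optional[str] = None) -> list[AptamerAnnotation]:
    """Load an aptamer annotation table.

    Unknown class/location/function tokens map to the unannotated/none
    fallback; the number of such rows is logged as a warning count.
    """
    path = Path(path)
    sep = _detect_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=list(MISSING_TOKENS),
                     keep_default_na=False)
    if "aptamer_id" not in df.columns:
        raise ValueError(f"missing required 'aptamer_id' column in {path}")
    unknown = {"n": 0}
    out = []
    for _, row in df.iterrows():
        def get(col, default=""):
            v = row.get(col)
            return default if v is None or (isinstance(v, float) and np.isnan(v)) else v

        gene = get("gene_symbol", "").strip()
        uniprot = get("uniprot", "").strip()
        out.append(
            AptamerAnnotation(
                aptamer_id=str(row["aptamer_id"]),
                target_full_name=get("target_full_name", ""),
                gene_symbol=gene or None,
                uniprot=uniprot or None,
                subcellular_class=_enum_or_fallback(
                    get("subcellular_class"), SubcellularClass,
                    SubcellularClass.UNANNOTATED, unknown),
                tissue_panels=_parse_set(get("tissue_panels")),
                immune_panels=_parse_set(get("immune_panels")),
                secretome_location=_enum_or_fallback(
                    get("secretome_location"), SecretomeLocation,
                    SecretomeLocation.NONE, unknown),
                secretome_function=_enum_or_fallback(
                    get("secretome_function"), SecretomeFunction,
                    SecretomeFunction.NONE, unknown),
                mito=_parse_bool(get("mito", "false")),
                neutrophil_release=_parse_bool(get("neutrophil_release", "false")),
            )
        )
    ids = [a.aptamer_id for a in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate aptamer ids in {path}")
    if unknown["n"]:
        warnings.warn(f"{unknown['n']} unrecognized annotation tokens mapped to fallback")
        logger.warning("%d unrecognized annotation tokens in %s", unknown["n"], path)
    return out


def load_sample_metadata(path, dialect: Optional[str] = None) -> list[SampleMetadata]:
    path = Path(path)
    sep = _detect_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, na_values=list(MISSING_TOKENS), keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"missing required 'sample_id' column in {path}")
    out = []
    for _, row in df.iterrows():
        def opt_float(col):
            v = row.get(col)
            try:
                v = float(v)
            except (TypeError, ValueError):
                return None
            return None if np.isnan(v) else v

        meta = str(row.get("metabotype") or "").strip()
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                sex=str(row.get("sex", "F")),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                fasting=_parse_bool(row.get("fasting", "false")),
                metabotype=meta or None,
                sf36pf=opt_float("sf36pf"),
                mean_steps=opt_float("mean_steps"),
                platform=str(row.get("platform", "aptamer") or "aptamer"),
            )
        )
    return out


def write_results_table(records, path, columns: Optional[Sequence[str]] = None) -> None:
    """Write a homogeneous record collection as a UTF-8 TSV.

    Accepts a DataFrame, a sequence of dataclasses, or a sequence of dicts.
    Column order is deterministic (first record's field order); floats keep
    full repr precision so write -> load round-trips exactly.  An empty
    collection yields a header-only file (pass ``columns`` to name the
    header when it cannot be inferred).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
        df = pd.DataFrame(rows, columns=columns) if (columns or not rows) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8",
              float_format=lambda v: repr(float(v)))


def load_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8", float_precision="round_trip")
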
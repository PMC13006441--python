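"""Core data types shared across the pipeline.

The central array is :class:`IntensityMatrix` (samples in rows, aptamers in
columns, strictly positive intensities with a per-cell status mask).
Aptamer identity/panel membership lives in :class:`AptamerAnnotation`,
sample-level covariates in :class:`SampleMetadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

# Per-cell mask codes for IntensityMatrix.mask
MASK_OBSERVED = 0
MASK_MISSING = 1
MASK_IMPUTED = 2


class SubcellularClass(str, Enum):
    INTRACELLULAR = "intracellular"
    MEMBRANE = "membrane"
    MEMBRANE_SECRETED = "membrane_secreted"
    SECRETED = "secreted"
    UNANNOTATED = "unannotated"


class SecretomeLocation(str, Enum):
    BLOOD = "blood"
    IC_M = "IC&M"
    ECM = "ECM"
    GI_TRACT = "GI_tract"
    BRAIN = "brain"
    MALE_RS = "male_RS"
    FEMALE_RS = "female_RS"
    OTHER_TISSUES = "other_tissues"
    UNKNOWN = "unknown"
    NONE = "none"


class SecretomeFunction(str, Enum):
    CPP = "CPP"
    ENZ = "Enz"
    HOR = "HOR"
    I_D = "I&D"
    INFL = "INFL"
    TR = "TR"
    OTHER = "other"
    NONE = "none"


@dataclass
class IntensityMatrix:
    """Samples x aptamers intensity matrix with a per-cell status mask.

    ``values`` is a float DataFrame indexed by sample id with aptamer ids as
    columns; observed cells must be strictly positive.  ``mask`` has the same
    shape and holds ``MASK_OBSERVED`` / ``MASK_MISSING`` / ``MASK_IMPUTED``.
    Missing cells carry NaN in ``values``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.mask is None:
            mask = pd.DataFrame(
                np.where(np.isfinite(self.values.to_numpy()), MASK_OBSERVED, MASK_MISSING),
                index=self.values.index,
                columns=self.values.columns,
                dtype=np.int8,
            )
            self.mask = mask
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate aptamer ids: {dups}")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape differs from values shape")
        obs = self.mask.to_numpy() == MASK_OBSERVED
        vals = self.values.to_numpy()
        bad = obs & ~(vals > 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                "non-positive observed intensity at sample "
                f"{self.values.index[i]!r}, aptamer {self.values.columns[j]!r}: {vals[i, j]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def aptamer_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def log10(self) -> pd.DataFrame:
        return np.log10(self.values)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.mask.copy())

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[sample_ids], self.mask.loc[sample_ids])

    def subset_aptamers(self, aptamer_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.values[aptamer_ids], self.mask[aptamer_ids])


@dataclass(frozen=True)
class AptamerAnnotation:
    """Identity and panel memberships of a single aptamer."""

    aptamer_id: str
    target_full_name: str = ""
    gene_symbol: Optional[str] = None
    uniprot: Optional[str] = None
    subcellular_class: SubcellularClass = SubcellularClass.UNANNOTATED
    tissue_panels: frozenset = field(default_factory=frozenset)
    immune_panels: frozenset = field(default_factory=frozenset)
    secretome_location: SecretomeLocation = SecretomeLocation.NONE
    secretome_function: SecretomeFunction = SecretomeFunction.NONE
    mito: bool = False
    neutrophil_release: bool = False


@dataclass(frozen=True)
class SampleMetadata:
    """Group label plus covariates for one sample on one platform."""

    sample_id: str
    group: str  # "ME" or "HC"
    sex: str = "F"
    age: float = 40.0
    bmi: float = 24.0
    fasting: bool = False
    metabotype: Optional[str] = None  # "M1" | "M2" | "M3" | None
    sf36pf: Optional[float] = None
    mean_steps: Optional[float] = None
    platform: str = "aptamer"

    def __post_init__(self) -> None:
        if self.group not in ("ME", "HC"):
            raise ValueError(f"unknown group {self.group!r}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not self.bmi > 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")


def metadata_frame(metadata) -> pd.DataFrame:
    """Tabulate a SampleMetadata collection, indexed by sample id."""
    rows = []
    for m in metadata:
        rows.append(
            {
                "sample_id": m.sample_id,
                "group": m.group,
                "sex": m.sex,
                "age": m.age,
                "bmi": m.bmi,
                "fasting": m.fasting,
                "metabotype": m.metabotype,
                "sf36pf": m.sf36pf,
                "mean_steps": m.mean_steps,
                "platform": m.platform,
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    return df


def annotation_frame(annotations) -> pd.DataFrame:
    """Tabulate an AptamerAnnotation collection, indexed by aptamer id."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "aptamer_id": a.aptamer_id,
                "target_full_name": a.target_full_name,
                "gene_symbol": a.gene_symbol,
                "uniprot": a.uniprot,
                "subcellular_class": a.subcellular_class.value,
                "tissue_panels": ";".join(sorted(a.tissue_panels)),
                "immune_panels": ";".join(sorted(a.immune_panels)),
                "secretome_location": a.secretome_location.value,
                "secretome_function": a.secretome_function.value,
                "mito": a.mito,
                "neutrophil_release": a.neutrophil_release,
            }
        )
    df = pd.DataFrame(rows).set_index("aptamer_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate aptamer ids in annotations")
    return df


__all__ = [
    "AptamerAnnotation",
    "IntensityMatrix",
    "SampleMetadata",
    "SecretomeFunction",
    "SecretomeLocation",
    "SubcellularClass",
    "MASK_OBSERVED",
    "MASK_MISSING",
    "MASK_IMPUTED",
    "annotation_frame",
    "metadata_frame",
    "replace",
]
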
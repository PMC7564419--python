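"""Shared domain types for the CNV-expression-survival funnel.

Conventions
-----------
* Genomic intervals (gene annotations, emitted segment BED) are stored
  0-based half-open, the BED convention.  Marker positions are 1-based, as
  printed in array annotation files.  Converters between the two are
  explicit at the I/O boundary; nothing downstream mixes conventions.
* Copy number is carried on the linear scale (diploid ~= 2) so that the
  deletion/gain window 1.72-2.78 applies directly to segment means.
* Expression matrices are log-scale, genes x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalRecord",
    "ExpressionMatrix",
    "CopyNumberMatrix",
    "MarkerTrack",
    "Segment",
    "GeneAnnotation",
    "AssociationRecord",
    "DoseResponseMatrix",
    "clinical_to_frame",
]

AssociationKind = Literal["GE~survival", "CNV~survival", "GE~CNV"]


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's survival record.

    ``survival_years`` is time from diagnosis to death (``event == 1``) or
    censoring (``event == 0``).  Optional covariates are ``None`` when the
    source table did not carry them; they are never imputed here — model
    fits perform listwise deletion and log the dropped count.
    """

    patient_id: str
    survival_years: float
    event: int
    metastasis_at_diagnosis: Optional[int] = None
    race: Optional[str] = None
    gender: Optional[str] = None
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.survival_years > 0:
            raise ValueError(
                f"patient {self.patient_id!r}: survival_years must be > 0, "
                f"got {self.survival_years}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"patient {self.patient_id!r}: event must be 0 or 1, got {self.event}"
            )
        if self.metastasis_at_diagnosis not in (None, 0, 1):
            raise ValueError(
                f"patient {self.patient_id!r}: metastasis_at_diagnosis must be "
                f"0/1/absent, got {self.metastasis_at_diagnosis}"
            )


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Tabulate clinical records, indexed by patient id (order preserved)."""
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_id(s): {dupes}")
    return pd.DataFrame(
        {
            "survival_years": [r.survival_years for r in records],
            "event": [r.event for r in records],
            "metastasis_at_diagnosis": [r.metastasis_at_diagnosis for r in records],
            "race": [r.race for r in records],
            "gender": [r.gender for r in records],
            "age_years": [r.age_years for r in records],
        },
        index=pd.Index(ids, name="patient_id"),
    )


class _LabelledMatrix:
    """Genes x samples matrix with unique row/column labels."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str).rename("gene")
        self.values.columns = self.values.columns.astype(str).rename(None)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"{type(self).__name__}({g} genes x {s} samples)"


class ExpressionMatrix(_LabelledMatrix):
    """Normalized log-scale expression, genes x samples; all values finite."""

    def __init__(self, values: pd.DataFrame):
        super().__init__(values)
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise ValueError(
                f"non-finite expression value at "
                f"({self.values.index[bad[0]]}, {self.values.columns[bad[1]]})"
            )


class CopyNumberMatrix(_LabelledMatrix):
    """Gene-level copy number, continuous (linear scale, > 0) or categorical.

    The categorical variant contains only {-1, 0, +1}: deletion / normal /
    gain.  Missing gene-level values (gene not covered by any segment) are
    NaN in the continuous variant and are flagged, never imputed.
    """

    def __init__(self, values: pd.DataFrame, categorical: bool = False):
        super().__init__(values)
        self.categorical = bool(categorical)
        arr = self.values.to_numpy()
        if self.categorical:
            ok = np.isin(arr, (-1.0, 0.0, 1.0)) | np.isnan(arr)
            if not ok.all():
                i, j = np.argwhere(~ok)[0]
                raise ValueError(
                    f"categorical copy number outside {{-1,0,+1}} at "
                    f"({self.values.index[i]}, {self.values.columns[j]}): {arr[i, j]}"
                )
        else:
            with np.errstate(invalid="ignore"):
                bad = arr <= 0
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"nonpositive copy number at "
                    f"({self.values.index[i]}, {self.values.columns[j]}): {arr[i, j]}"
                )

    @property
    def missing_genes(self) -> list[str]:
        mask = self.values.isna().any(axis=1)
        return list(self.values.index[mask])


@dataclass
class MarkerTrack:
    """Ordered per-marker copy-number intensities for one sample.

    ``markers`` is a frame with columns (chromosome, position, copy_number);
    positions are 1-based and strictly increasing within a chromosome, copy
    number is linear-scale (> 0).
    """

    sample_id: str
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chromosome", "position", "copy_number"}
        if not need.issubset(self.markers.columns):
            raise ValueError(f"marker frame must have columns {sorted(need)}")
        if (self.markers["copy_number"] <= 0).any():
            raise ValueError(f"sample {self.sample_id!r}: nonpositive marker copy number")
        for chrom, grp in self.markers.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"sample {self.sample_id!r}: positions not strictly increasing "
                    f"on {chrom}"
                )

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chromosome"]))


@dataclass(frozen=True)
class Segment:
    """A run of markers with constant mean copy number.

    ``start_pos``/``end_pos`` are the 1-based positions of the first and last
    marker in the segment (inclusive).
    """

    sample_id: str
    chromosome: str
    start_pos: int
    end_pos: int
    n_markers: int
    mean_copy_number: float

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("segment start_pos > end_pos")
        if self.n_markers < 1:
            raise ValueError("segment with no markers")
        if not self.mean_copy_number > 0:
            raise ValueError("segment mean copy number must be positive")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene interval, 0-based half-open (BED convention)."""

    symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.symbol!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssociationRecord:
    """One gene's effect estimate from a screen.

    ``beta`` is the log hazard (survival kinds) or the regression slope
    (GE~CNV); ``hazard_ratio`` is exp(beta) for survival kinds and None
    otherwise.  ``direction`` is the sign of beta.  ``estimable`` is False
    when the fit failed (constant exposure, monotone likelihood); such
    records never enter a significant set.
    """

    gene: str
    kind: AssociationKind
    beta: float
    se: float
    p_value: float
    hazard_ratio: Optional[float] = None
    direction: int = 0
    n_used: int = 0
    n_events: Optional[int] = None
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable:
            if not (0.0 < self.p_value <= 1.0):
                raise ValueError(f"gene {self.gene!r}: p_value outside (0,1]")
            if self.hazard_ratio is not None and not self.hazard_ratio > 0:
                raise ValueError(f"gene {self.gene!r}: hazard_ratio must be > 0")
            if self.beta != 0 and self.direction != int(np.sign(self.beta)):
                raise ValueError(f"gene {self.gene!r}: direction != sign(beta)")


def associations_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Tabulate association records, indexed by gene symbol."""
    return pd.DataFrame(
        {
            "kind": [r.kind for r in records],
            "beta": [r.beta for r in records],
            "hazard_ratio": [r.hazard_ratio for r in records],
            "se": [r.se for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
            "n_used": [r.n_used for r in records],
            "n_events": [r.n_events for r in records],
            "estimable": [r.estimable for r in records],
        },
        index=pd.Index([r.gene for r in records], name="gene"),
    )


@dataclass
class DoseResponseMatrix:
    """Checkerboard of fraction-affected values over two drugs' dose grids.

    ``doses_a``/``doses_b`` are strictly increasing and include 0 as the
    first entry when single-agent margins are encoded (dose 0 of the
    partner).  ``effects`` has shape (replicates, len(doses_a),
    len(doses_b)); a single replicate may be passed as a 2-D array.  Values
    are growth inhibition relative to vehicle, in [0, 1].
    """

    drug_a_name: str
    drug_b_name: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    effects: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.ndim == 2:
            self.effects = self.effects[None, :, :]
        for name, doses in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if doses.ndim != 1 or not (np.diff(doses) > 0).all():
                raise ValueError(f"{name} must be 1-D strictly increasing")
            if (doses < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        if self.effects.shape[1:] != (len(self.doses_a), len(self.doses_b)):
            raise ValueError(
                f"effects shape {self.effects.shape[1:]} does not match dose grids "
                f"({len(self.doses_a)}, {len(self.doses_b)})"
            )
        if ((self.effects < 0) | (self.effects > 1)).any():
            raise ValueError("effects must lie in [0, 1]")

    @property
    def n_replicates(self) -> int:
        return self.effects.shape[0]

    @property
    def has_margins(self) -> bool:
        return self.doses_a[0] == 0.0 and self.doses_b[0] == 0.0

    def mean_effects(self) -> np.ndarray:
        return self.effects.mean(axis=0)
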
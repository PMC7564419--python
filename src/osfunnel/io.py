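"""Readers and writers for the tabular formats the pipeline touches.

All tables are plain text: TSV matrices (first column ``gene``, header row
of sample ids), a clinical TSV with documented required headers, BED4 gene
annotations, marker-track TSV, and dose-matrix CSV.  Readers never silently
coerce or drop rows; every rejection names the offending row or cell.
Writer/reader pairs round-trip values and labels exactly.
"""

from __future__ import annotations

import os
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalRecord,
    CopyNumberMatrix,
    DoseResponseMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    MarkerTrack,
    Segment,
)

PathLike = Union[str, os.PathLike]

CLINICAL_REQUIRED = ("patient_id", "survival_years", "event")
CLINICAL_OPTIONAL = ("metastasis_at_diagnosis", "race", "gender", "age_years")


def read_clinical(path: PathLike) -> list[ClinicalRecord]:
    """Read a clinical TSV into records.

    Required columns: patient_id, survival_years, event.  Optional:
    metastasis_at_diagnosis, race, gender, age_years.  Missing optional
    fields stay absent (None); duplicate ids and nonpositive survival times
    are hard errors naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str},
                     float_precision="round_trip")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s): {missing}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dupes))}")

    records = []
    for _, row in df.iterrows():
        def opt(col, cast=lambda x: x):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                survival_years=float(row["survival_years"]),
                event=int(row["event"]),
                metastasis_at_diagnosis=opt("metastasis_at_diagnosis", int),
                race=opt("race", str),
                gender=opt("gender", str),
                age_years=opt("age_years", float),
            )
        )
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "survival_years": r.survival_years,
                "event": r.event,
                "metastasis_at_diagnosis": r.metastasis_at_diagnosis,
                "race": r.race,
                "gender": r.gender,
                "age_years": r.age_years,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_MATRIX_KINDS = ("expression", "copy_number_continuous", "copy_number_categorical")


def read_matrix(path: PathLike, kind: str):
    """Read a genes-x-samples TSV (first column ``gene``).

    ``kind`` selects the container and its validation: ``expression``,
    ``copy_number_continuous`` or ``copy_number_categorical``.  Non-numeric
    cells are reported with (gene, sample) coordinates.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"kind must be one of {_MATRIX_KINDS}, got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at ({df.index[i]}, {df.columns[j]}): {df.iat[i, j]!r}"
        )
    if kind == "expression":
        return ExpressionMatrix(numeric)
    return CopyNumberMatrix(numeric, categorical=kind == "copy_number_categorical")


def write_matrix(matrix, path: PathLike) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_annotation_bed(path: PathLike) -> list[GeneAnnotation]:
    """Read a 4-column BED (chrom, start, end, symbol), 0-based half-open.

    Output is sorted by (chromosome, start); start >= end and duplicate
    symbols are hard errors.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "symbol"],
        dtype={"chromosome": str, "symbol": str},
        comment="#",
    )
    dupes = df["symbol"][df["symbol"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate gene symbol(s): {sorted(set(dupes))}")
    annotations = [
        GeneAnnotation(
            symbol=row.symbol,
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
        )
        for row in df.itertuples()
    ]
    return sorted(annotations, key=lambda a: (a.chromosome, a.start, a.symbol))


def write_annotation_bed(annotations: Sequence[GeneAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for a in sorted(annotations, key=lambda a: (a.chromosome, a.start, a.symbol)):
            fh.write(f"{a.chromosome}\t{a.start}\t{a.end}\t{a.symbol}\n")


def read_marker_tracks(path: PathLike) -> list[MarkerTrack]:
    """Read marker-level copy number TSV (sample, chromosome, position, copy_number)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    need = {"sample", "chromosome", "position", "copy_number"}
    if not need.issubset(df.columns):
        raise ValueError(f"marker track table must have columns {sorted(need)}")
    tracks = []
    for sample, grp in df.groupby("sample", sort=False):
        tracks.append(
            MarkerTrack(
                sample_id=sample,
                markers=grp[["chromosome", "position", "copy_number"]].reset_index(
                    drop=True
                ),
            )
        )
    return tracks


def write_marker_tracks(tracks: Sequence[MarkerTrack], path: PathLike) -> None:
    frames = []
    for t in tracks:
        frame = t.markers.copy()
        frame.insert(0, "sample", t.sample_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_segments(segments: Sequence[Segment], path: PathLike) -> None:
    """Write segments as BED-like TSV (chrom, start0, end0, sample, n_markers, mean_cn).

    Marker positions are 1-based inclusive internally; the emitted interval
    is converted to the 0-based half-open BED convention.
    """
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tsample\tn_markers\tmean_copy_number\n")
        for s in segments:
            fh.write(
                f"{s.chromosome}\t{s.start_pos - 1}\t{s.end_pos}\t{s.sample_id}"
                f"\t{s.n_markers}\t{s.mean_copy_number:.6g}\n"
            )


def read_segments(path: PathLike) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "sample": str})
    return [
        Segment(
            sample_id=row.sample,
            chromosome=row.chromosome,
            start_pos=int(row.start) + 1,
            end_pos=int(row.end),
            n_markers=int(row.n_markers),
            mean_copy_number=float(row.mean_copy_number),
        )
        for row in df.itertuples()
    ]


def read_dose_matrix(
    paths: Union[PathLike, Sequence[PathLike]],
    drug_a_name: str = "drug_a",
    drug_b_name: str = "drug_b",
) -> DoseResponseMatrix:
    """Read one or more replicate dose-matrix CSVs and stack them.

    Layout: first row and first column are the dose grids (uM); the top-left
    cell is ignored; interior cells are fraction affected in [0, 1].  A dose
    of 0 in the first row/column encodes the single-agent margin of the
    other drug.  All replicates must share the same dose grids.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    stacks, grids = [], None
    for p in paths:
        df = pd.read_csv(p, header=None)
        doses_a = df.iloc[1:, 0].astype(float).to_numpy()
        doses_b = df.iloc[0, 1:].astype(float).to_numpy()
        vals = df.iloc[1:, 1:].astype(float).to_numpy()
        if grids is None:
            grids = (doses_a, doses_b)
        elif not (
            np.array_equal(grids[0], doses_a) and np.array_equal(grids[1], doses_b)
        ):
            raise ValueError(f"replicate {p} has mismatched dose grids")
        stacks.append(vals)
    return DoseResponseMatrix(
        drug_a_name=drug_a_name,
        drug_b_name=drug_b_name,
        doses_a=grids[0],
        doses_b=grids[1],
        effects=np.stack(stacks),
    )


def write_dose_matrix(matrix: DoseResponseMatrix, path: PathLike, replicate: int = 0) -> None:
    vals = matrix.effects[replicate]
    out = np.zeros((len(matrix.doses_a) + 1, len(matrix.doses_b) + 1))
    out[0, 1:] = matrix.doses_b
    out[1:, 0] = matrix.doses_a
    out[1:, 1:] = vals
    pd.DataFrame(out).to_csv(path, header=False, index=False)
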
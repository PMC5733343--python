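"""Compound-library annotation of LC-MS features by exact mass.

Features observed as [M-H]- ions are neutralized and compared against the
theoretical monoisotopic masses of a willow-bark compound library (58
entries transcribed from the study's identification table), within a ppm
tolerance and optionally a retention-time window.  Matching always uses
the formula-derived theoretical mass, not the printed observed mass:
a few library rows carry a curation note because their printed mass and
printed formula are mutually inconsistent, and those printed values are
kept verbatim rather than silently corrected.

Fragmentation-spectrum matching and structure elucidation are out of
scope; isobaric compounds can only be separated by retention time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import chem

__all__ = [
    "IdentificationLevel",
    "CompoundRecord",
    "AnnotationHit",
    "load_library",
    "match_feature",
    "annotate_table",
]


class IdentificationLevel(str, enum.Enum):
    REFERENCE_COMPOUND = "reference"  # confirmed with an authentic standard
    TENTATIVE = "tentative"  # mass/formula/fragmentation literature match


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry with printed values and the formula-derived mass."""

    peak_id: int
    name: str
    formula: chem.Formula
    rt: float
    printed_mass: float
    printed_delta_ppm: float
    identification_level: IdentificationLevel
    salix_described: bool
    known_gut_metabolite: bool
    curation_note: str | None = None

    @property
    def theoretical_mass(self) -> float:
        return chem.monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: object
    peak_id: int
    name: str
    delta_ppm: float
    delta_rt: float | None


def load_library(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load the compound library (the bundled willow-bark table by default).

    Raises a descriptive error naming the offending row on duplicate peak
    ids or unparseable formulas.
    """
    if path is None:
        source = resources.files("salixfate.data").joinpath("compound_library.tsv")
        with resources.as_file(source) as fp:
            frame = pd.read_csv(fp, sep="\t", dtype={"curation_note": "string"})
    else:
        frame = pd.read_csv(path, sep="\t", dtype={"curation_note": "string"})
    if frame.empty:
        raise ValueError("compound library is empty")
    required = {"peak_id", "name", "rt_min", "printed_mass_da", "formula"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"compound library is missing columns {sorted(missing)}")
    records: list[CompoundRecord] = []
    seen: set[int] = set()
    for _, row in frame.iterrows():
        peak_id = int(row["peak_id"])
        if peak_id in seen:
            raise ValueError(f"duplicate peak_id {peak_id} in compound library")
        seen.add(peak_id)
        try:
            formula = chem.parse_formula(row["formula"])
        except chem.FormulaError as exc:
            raise ValueError(f"library row {peak_id}: {exc}") from exc
        rt = float(row["rt_min"])
        if rt <= 0:
            raise ValueError(f"library row {peak_id}: non-positive retention time")
        note = row.get("curation_note")
        records.append(
            CompoundRecord(
                peak_id=peak_id,
                name=str(row["name"]),
                formula=formula,
                rt=rt,
                printed_mass=float(row["printed_mass_da"]),
                printed_delta_ppm=float(row.get("printed_delta_ppm", math.nan)),
                identification_level=IdentificationLevel(
                    str(row.get("identification_level", "tentative"))
                ),
                salix_described=bool(int(row.get("salix_described", 0))),
                known_gut_metabolite=bool(int(row.get("known_gut_metabolite", 0))),
                curation_note=None if pd.isna(note) else str(note),
            )
        )
    return records


def match_feature(
    mz: float,
    rt: float | None,
    library: Sequence[CompoundRecord],
    ppm_tol: float = 5.0,
    rt_tol: float | None = None,
    feature_id: object = None,
) -> list[AnnotationHit]:
    """Rank library compounds matching one feature by exact mass.

    The feature's neutral mass (m/z plus proton mass) is compared with
    each record's theoretical mass; candidates within ``ppm_tol`` (and
    within ``rt_tol`` minutes when retention-time gating is enabled) are
    returned sorted by \\|delta ppm\\|, then \\|delta RT\\|, then peak id.
    An empty list is a valid result.
    """
    neutral = chem.neutral_from_negmode_mz(mz)
    hits: list[AnnotationHit] = []
    for rec in library:
        delta_ppm = chem.ppm_delta(neutral, rec.theoretical_mass)
        if abs(delta_ppm) > ppm_tol:
            continue
        delta_rt = None if rt is None else rt - rec.rt
        if rt_tol is not None and delta_rt is not None and abs(delta_rt) > rt_tol:
            continue
        hits.append(
            AnnotationHit(
                feature_id=feature_id,
                peak_id=rec.peak_id,
                name=rec.name,
                delta_ppm=delta_ppm,
                delta_rt=delta_rt,
            )
        )
    hits.sort(
        key=lambda h: (
            abs(h.delta_ppm),
            abs(h.delta_rt) if h.delta_rt is not None else 0.0,
            h.peak_id,
        )
    )
    return hits


def annotate_table(
    table,
    library: Sequence[CompoundRecord] | None = None,
    ppm_tol: float = 5.0,
    rt_tol: float | None = None,
) -> pd.DataFrame:
    """Annotate every feature of a table; one row per hit."""
    if library is None:
        library = load_library()
    rows = []
    for fid, meta in table.features.iterrows():
        for hit in match_feature(
            meta["mz"], meta["rt"], library, ppm_tol, rt_tol, feature_id=fid
        ):
            rows.append(
                {
                    "feature_id": fid,
                    "peak_id": hit.peak_id,
                    "name": hit.name,
                    "delta_ppm": hit.delta_ppm,
                    "delta_rt": hit.delta_rt,
                }
            )
    return pd.DataFrame(rows, columns=["feature_id", "peak_id", "name", "delta_ppm", "delta_rt"])
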
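"""On-disk formats for multi-region tumour sequencing analysis.

Three canonical tabular/structured dialects are defined here and used by
every other module:

* **variant TSV** (MAF-like): one row per somatic SNV observed (or assayed)
  in one tumour region, with read counts and annotations.
* **segment TSV** (SEG-like): one row per allele-specific copy-number
  segment in one region. Coordinates are 1-based inclusive on disk; all
  interval arithmetic elsewhere in the package uses half-open 0-based
  intervals, converted at this boundary.
* **sample sheet** (YAML): per-patient clinical annotation (clinical group,
  Gleason grade, optional neoantigen burdens) and per-region purity and
  immune counts.

Round-trip stability (``read(write(x)) == x``) is guaranteed for all three,
and unknown columns in the TSV files are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

__all__ = [
    "VARIANT_COLUMNS",
    "SEGMENT_COLUMNS",
    "EFFECT_CLASSES",
    "SampleSheet",
    "SchemaError",
    "ValidationError",
    "read_variants",
    "write_variants",
    "read_segments",
    "write_segments",
    "read_sheet",
    "write_sheet",
    "write_results",
    "read_results",
    "validate_segments",
    "SegmentLookup",
]

#: Required columns of the variant TSV, in canonical write order.
VARIANT_COLUMNS = [
    "patient_id",
    "region_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "gene",
    "effect",
    "context",
    "germline_flag",
]

#: Required columns of the segment TSV, in canonical write order.
SEGMENT_COLUMNS = [
    "patient_id",
    "region_id",
    "chrom",
    "start",
    "end",
    "major_cn",
    "minor_cn",
]

EFFECT_CLASSES = {"missense", "nonsense", "frameshift", "silent", "other"}


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """File parses but violates a semantic invariant (e.g. overlapping segments)."""


@dataclass
class SampleSheet:
    """Clinical and immune annotation for a cohort.

    ``patients`` maps patient id to a dict with keys ``group`` (``mHNPC`` or
    ``hrlPC``), ``gleason``, optional ``neoantigen_burden`` and
    ``clonal_neoantigen_burden``, and ``regions`` — a mapping from region id
    to per-region annotation (``purity``, ``inif_percent``, ``cd8``, ``cd4``,
    ``foxp3``).
    """

    patients: dict[str, dict[str, Any]] = field(default_factory=dict)

    def region_ids(self, patient_id: str) -> list[str]:
        return list(self.patients[patient_id]["regions"])

    def purity(self, patient_id: str, region_id: str) -> float:
        return float(self.patients[patient_id]["regions"][region_id]["purity"])

    def group(self, patient_id: str) -> str:
        return str(self.patients[patient_id]["group"])

    def validate(self) -> None:
        for pid, rec in self.patients.items():
            if rec.get("group") not in {"mHNPC", "hrlPC"}:
                raise ValidationError(
                    f"patient {pid}: clinical group must be mHNPC or hrlPC, "
                    f"got {rec.get('group')!r}"
                )
            regions = rec.get("regions") or {}
            if not regions:
                raise ValidationError(f"patient {pid}: no regions in sheet")
            for rid, reg in regions.items():
                purity = reg.get("purity")
                if purity is None or not (0.0 < float(purity) <= 1.0):
                    raise ValidationError(
                        f"patient {pid} region {rid}: purity must be in (0, 1], "
                        f"got {purity!r}"
                    )
                inif = reg.get("inif_percent")
                if inif is not None and not (0.0 <= float(inif) <= 100.0):
                    raise ValidationError(
                        f"patient {pid} region {rid}: INIF percent outside [0, 100]: {inif!r}"
                    )

    def check_regions_covered(self, table: pd.DataFrame) -> None:
        """Every (patient, region) referenced by a table must appear in the sheet."""
        seen = set(zip(table["patient_id"], table["region_id"]))
        known = {
            (pid, rid)
            for pid, rec in self.patients.items()
            for rid in (rec.get("regions") or {})
        }
        missing = sorted(seen - known)
        if missing:
            raise ValidationError(f"regions absent from sample sheet: {missing}")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {missing}")


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a variant TSV into a DataFrame (one row per SNV per region)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, VARIANT_COLUMNS, "variant")
    if len(df):
        df["pos"] = df["pos"].astype(int)
        df["ref_count"] = df["ref_count"].astype(int)
        df["alt_count"] = df["alt_count"].astype(int)
        df["germline_flag"] = df["germline_flag"].astype(bool)
        df["gene"] = df["gene"].fillna("").astype(str)
        df["context"] = df["context"].fillna("").astype(str)
        if "protein_change" in df.columns:
            df["protein_change"] = df["protein_change"].fillna("").astype(str)
        if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
            raise ValidationError("negative read counts in variant file")
        bad = sorted(set(df["effect"]) - EFFECT_CLASSES)
        if bad:
            raise ValidationError(f"unknown effect class(es): {bad}")
    return df


def write_variants(path: str | Path, df: pd.DataFrame) -> None:
    """Write a variant table; canonical columns first, extras preserved after."""
    _require_columns(df, VARIANT_COLUMNS, "variant")
    extra = [c for c in df.columns if c not in VARIANT_COLUMNS]
    df[VARIANT_COLUMNS + extra].to_csv(path, sep="\t", index=False)


def validate_segments(df: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on malformed or overlapping segments."""
    if len(df) == 0:
        return
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise ValidationError(
            f"segment with start > end: {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    if (df["major_cn"] < 0).any() or (df["minor_cn"] < 0).any():
        raise ValidationError("negative copy number in segment file")
    if (df["major_cn"] < df["minor_cn"]).any():
        raise ValidationError("major_cn < minor_cn in segment file")
    for (pid, rid, chrom), grp in df.groupby(
        ["patient_id", "region_id", "chrom"], sort=False
    ):
        grp = grp.sort_values("start")
        prev_end = grp["end"].shift()
        prev_start = grp["start"].shift()
        overlap = grp["start"] <= prev_end
        if overlap.any():
            i = overlap.idxmax()
            raise ValidationError(
                f"overlapping segments in {pid}/{rid} on {chrom}: "
                f"{int(prev_start.loc[i])}-{int(prev_end.loc[i])} and "
                f"{int(grp.loc[i, 'start'])}-{int(grp.loc[i, 'end'])}"
            )


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-like TSV (1-based inclusive coordinates) and validate it."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, SEGMENT_COLUMNS, "segment")
    if len(df):
        for col in ("start", "end", "major_cn", "minor_cn"):
            df[col] = df[col].astype(int)
    validate_segments(df)
    return df


def write_segments(path: str | Path, df: pd.DataFrame) -> None:
    _require_columns(df, SEGMENT_COLUMNS, "segment")
    extra = [c for c in df.columns if c not in SEGMENT_COLUMNS]
    df[SEGMENT_COLUMNS + extra].to_csv(path, sep="\t", index=False)


def read_sheet(path: str | Path) -> SampleSheet:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "patients" not in raw:
        raise SchemaError("sample sheet is missing required top-level key 'patients'")
    sheet = SampleSheet(patients=raw["patients"] or {})
    sheet.validate()
    return sheet


def write_sheet(path: str | Path, sheet: SampleSheet) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"patients": sheet.patients}, fh, sort_keys=True)


def write_results(path: str | Path, results: dict[str, Any]) -> None:
    """Write an analysis results dict as JSON (numpy scalars coerced)."""
    import json

    import numpy as np

    def _coerce(obj: Any) -> Any:
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_coerce)
        fh.write("\n")


def read_results(path: str | Path) -> dict[str, Any]:
    import json

    with open(path) as fh:
        return json.load(fh)


class SegmentLookup:
    """Fast (region, chrom, pos) -> (total_cn, major_cn) over a segment table.

    Positions not covered by any segment fall back to a diploid
    heterozygous state (total 2, major 1).
    """

    def __init__(self, segments: pd.DataFrame):
        import numpy as np

        self._np = np
        self._idx: dict[tuple[str, str], tuple] = {}
        if len(segments) == 0:
            return
        for (rid, chrom), grp in segments.groupby(["region_id", "chrom"], sort=False):
            grp = grp.sort_values("start")
            self._idx[(rid, chrom)] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                (grp["major_cn"] + grp["minor_cn"]).to_numpy(),
                grp["major_cn"].to_numpy(),
            )

    def at(self, region_id: str, chrom: str, pos: int) -> tuple[int, int]:
        entry = self._idx.get((region_id, chrom))
        if entry is None:
            return 2, 1
        starts, ends, total, major = entry
        i = int(self._np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or ends[i] < pos:
            return 2, 1
        return int(total[i]), int(major[i])


# -- coordinate convention helpers --------------------------------------------
# On disk: 1-based inclusive (SEG convention). In memory for interval math:
# 0-based half-open.

def to_halfopen(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_1based_inclusive


def to_inclusive(start_0based: int, end_halfopen: int) -> tuple[int, int]:
    return start_0based + 1, end_halfopen
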
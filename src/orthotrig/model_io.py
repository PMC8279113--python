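"""Data model and I/O: arch models, IGES point extraction, CSV tables.

The pipeline's canonical interchange format is plain CSV.  IGES files (the
export of a mesh-inspection tool after manual point picking) are
import-only: Type-116 point entities are read in directory-entry order and
mapped to (patient, arch, timepoint, tooth, landmark) through a sidecar
manifest, because IGES entity labels do not reliably carry identity.

Coordinates are millimetres in a right-handed frame throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MalformedFileError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkKind",
    "ToothLandmarks",
    "ArchModel",
    "LANDMARK_ORDER",
    "LANDMARK_COLUMNS",
    "tooth_type",
    "is_second_molar",
    "parse_iges_points",
    "landmarks_from_iges",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_tables",
]


class LandmarkKind(str, Enum):
    """The five landmarks picked on each tooth crown."""

    LINGUAL_GINGIVAL = "lingual_gingival"
    MESIAL = "mesial"
    DISTAL = "distal"
    OCCLUSAL = "occlusal"
    VESTIBULAR_GINGIVAL = "vestibular_gingival"


#: Fixed landmark ordering used for CSV columns and point stacking.
LANDMARK_ORDER: tuple[LandmarkKind, ...] = (
    LandmarkKind.LINGUAL_GINGIVAL,
    LandmarkKind.MESIAL,
    LandmarkKind.DISTAL,
    LandmarkKind.OCCLUSAL,
    LandmarkKind.VESTIBULAR_GINGIVAL,
)

LANDMARK_COLUMNS = [
    "patient_id",
    "arch",
    "timepoint",
    "tooth_fdi",
    "landmark",
    "x_mm",
    "y_mm",
    "z_mm",
]

_ARCHES = ("upper", "lower")
_TIMEPOINTS = ("initial", "final_planned")


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ValidationError(f"not a finite 3D point: {p!r}")
    return a


def tooth_type(fdi: int) -> str:
    """Classify an FDI code into incisor / canine / premolar / molar."""
    digit = fdi % 10
    if digit in (1, 2):
        return "incisor"
    if digit == 3:
        return "canine"
    if digit in (4, 5):
        return "premolar"
    if digit in (6, 7, 8):
        return "molar"
    raise ValidationError(f"invalid FDI tooth code: {fdi}")


def is_second_molar(fdi: int) -> bool:
    return fdi % 10 == 7


@dataclass
class ToothLandmarks:
    """The five landmark coordinates (mm) of one tooth.

    Parameters
    ----------
    tooth_id : int
        Two-digit FDI code (11-48).
    landmarks : mapping of LandmarkKind to array-like of shape (3,)
    """

    tooth_id: int
    landmarks: dict[LandmarkKind, np.ndarray]

    def __post_init__(self):
        self.tooth_id = int(self.tooth_id)
        tooth_type(self.tooth_id)  # validates the code
        lm = {LandmarkKind(k): _as_point(v) for k, v in self.landmarks.items()}
        missing = [k for k in LANDMARK_ORDER if k not in lm]
        if missing:
            raise ValidationError(
                f"tooth {self.tooth_id}: missing landmark(s) "
                + ", ".join(k.name for k in missing)
            )
        if np.allclose(lm[LandmarkKind.MESIAL], lm[LandmarkKind.DISTAL]):
            raise ValidationError(
                f"tooth {self.tooth_id}: mesial and distal landmarks coincide"
            )
        if np.allclose(
            lm[LandmarkKind.OCCLUSAL], lm[LandmarkKind.VESTIBULAR_GINGIVAL]
        ):
            raise ValidationError(
                f"tooth {self.tooth_id}: occlusal and vestibular gingival "
                "landmarks coincide"
            )
        self.landmarks = lm

    def __getitem__(self, kind: LandmarkKind) -> np.ndarray:
        return self.landmarks[LandmarkKind(kind)]

    def points(self) -> np.ndarray:
        """Stack the five landmarks as a (5, 3) array in LANDMARK_ORDER."""
        return np.stack([self.landmarks[k] for k in LANDMARK_ORDER])

    def with_points(self, pts: np.ndarray) -> "ToothLandmarks":
        """Rebuild the tooth from a (5, 3) array in LANDMARK_ORDER."""
        pts = np.asarray(pts, dtype=float)
        return ToothLandmarks(
            self.tooth_id, dict(zip(LANDMARK_ORDER, pts))
        )


@dataclass
class ArchModel:
    """All landmarked teeth of one arch of one patient at one timepoint."""

    patient_id: str
    arch: str
    timepoint: str
    teeth: dict[int, ToothLandmarks] = field(default_factory=dict)

    def __post_init__(self):
        if self.arch not in _ARCHES:
            raise ValidationError(f"arch must be one of {_ARCHES}: {self.arch!r}")
        if self.timepoint not in _TIMEPOINTS:
            raise ValidationError(
                f"timepoint must be one of {_TIMEPOINTS}: {self.timepoint!r}"
            )
        quadrants = (1, 2) if self.arch == "upper" else (3, 4)
        for fdi, tooth in self.teeth.items():
            if int(fdi) != tooth.tooth_id:
                raise ValidationError(
                    f"tooth key {fdi} != tooth_id {tooth.tooth_id}"
                )
            if tooth.tooth_id // 10 not in quadrants:
                raise ValidationError(
                    f"tooth {tooth.tooth_id} is not an {self.arch}-arch code"
                )

    def tooth_ids(self) -> list[int]:
        return list(self.teeth)

    def map_points(self, fn) -> "ArchModel":
        """Apply ``fn((n,3) array) -> (n,3) array`` to every tooth's landmarks."""
        teeth = {
            fdi: t.with_points(fn(t.points())) for fdi, t in self.teeth.items()
        }
        return ArchModel(self.patient_id, self.arch, self.timepoint, teeth)


# ---------------------------------------------------------------------------
# IGES reading (Type 116 point entities only)
# ---------------------------------------------------------------------------

_HOLLERITH = re.compile(r"^(\d+)H")


def _tokenize(text: str, pdelim: str, rdelim: str) -> list[str]:
    """Split an IGES free-format record into fields.

    Handles Hollerith string constants (``nHxxxx``) whose payload may
    contain delimiter characters.  Stops at the record delimiter.
    """
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        m = _HOLLERITH.match(text[i:])
        if m:
            ln = int(m.group(1))
            start = i + m.end()
            tokens.append(text[start : start + ln])
            i = start + ln
        else:
            j = i
            while j < n and text[j] not in (pdelim, rdelim):
                j += 1
            tokens.append(text[i:j].strip())
            i = j
        if i >= n:
            break
        if text[i] == rdelim:
            break
        if text[i] == pdelim:
            i += 1
    return tokens


def _parse_global(text: str) -> tuple[str, str, list[str]]:
    """Return (parameter delimiter, record delimiter, remaining fields)."""
    i = 0
    pdelim = ","
    if text[:1] == ",":
        i = 1
    else:
        m = _HOLLERITH.match(text)
        if m:
            ln = int(m.group(1))
            pdelim = text[m.end() : m.end() + ln]
            i = m.end() + ln
            if text[i : i + 1] == pdelim:
                i += 1
    rdelim = ";"
    rest = text[i:]
    if rest[:1] == pdelim:
        rest = rest[1:]
    else:
        m = _HOLLERITH.match(rest)
        if m:
            ln = int(m.group(1))
            rdelim = rest[m.end() : m.end() + ln]
            rest = rest[m.end() + ln :]
            if rest[:1] == pdelim:
                rest = rest[1:]
    if len(pdelim) != 1 or len(rdelim) != 1:
        raise MalformedFileError(
            f"invalid IGES delimiters: {pdelim!r}, {rdelim!r}"
        )
    return pdelim, rdelim, _tokenize(rest, pdelim, rdelim)


def parse_iges_points(file_content: str) -> list[tuple[str, np.ndarray]]:
    """Extract Type-116 (Point) entities from an IGES 5.x file.

    Parameters
    ----------
    file_content : str
        Full text of a fixed-80-column IGES file.

    Returns
    -------
    list of (label, (3,) ndarray)
        One entry per point entity, in directory-entry order; the label is
        the directory entry's (possibly blank) label field.

    Raises
    ------
    MalformedFileError
        If the Terminate section is missing, a section is structurally
        broken, or a coordinate field fails to parse (the error names the
        offending directory-entry sequence number).  Entities other than
        Type 116 are skipped with a logged warning.  The Global units flag
        must be millimetres (2) or absent.
    """
    sections: dict[str, list[str]] = {c: [] for c in "SGDPT"}
    for raw in file_content.splitlines():
        if not raw.strip():
            continue
        line = raw.ljust(80)
        code = line[72]
        if code not in sections:
            raise MalformedFileError(f"unknown IGES section code {code!r}")
        sections[code].append(line)
    if not sections["T"]:
        raise MalformedFileError("IGES file has no Terminate section")

    gtext = "".join(ln[:72] for ln in sections["G"]).rstrip()
    pdelim, rdelim, gfields = _parse_global(gtext) if gtext else (",", ";", [])
    # Global field 14 (units flag) follows the two delimiter fields.
    if len(gfields) >= 12 and gfields[11]:
        try:
            units = int(gfields[11])
        except ValueError:
            raise MalformedFileError(f"unreadable IGES units flag {gfields[11]!r}")
        if units != 2:
            raise MalformedFileError(
                f"IGES units flag {units} is not millimetres (2); "
                "no unit conversion is performed"
            )

    # Parameter section lines keyed by their own sequence numbers.
    pdata: dict[int, str] = {}
    for ln in sections["P"]:
        try:
            seq = int(ln[73:80])
        except ValueError:
            raise MalformedFileError(f"bad P-section sequence number: {ln[73:80]!r}")
        pdata[seq] = ln[:64]

    dlines = sections["D"]
    if len(dlines) % 2:
        raise MalformedFileError("IGES directory section has an odd line count")

    out: list[tuple[str, np.ndarray]] = []
    for first, second in zip(dlines[0::2], dlines[1::2]):
        de_seq = int(first[73:80])
        try:
            etype = int(first[0:8])
            pd_ptr = int(first[8:16])
            pd_count = int(second[24:32])
        except ValueError:
            raise MalformedFileError(
                f"unreadable directory entry at sequence {de_seq}"
            )
        label = second[56:64].strip()
        if etype != 116:
            logger.warning(
                "skipping IGES entity type %d at DE %d (only Type 116 points "
                "are supported)", etype, de_seq,
            )
            continue
        try:
            record = "".join(pdata[pd_ptr + i] for i in range(max(pd_count, 1)))
        except KeyError:
            raise MalformedFileError(
                f"missing parameter data for directory entry {de_seq}"
            )
        fields = _tokenize(record, pdelim, rdelim)
        if not fields or fields[0].strip() != "116":
            raise MalformedFileError(
                f"parameter record of DE {de_seq} does not start with 116"
            )
        try:
            xyz = np.array([float(fields[k]) for k in (1, 2, 3)])
        except (ValueError, IndexError):
            raise MalformedFileError(
                f"non-numeric coordinate in point entity at directory entry {de_seq}"
            )
        out.append((label, xyz))
    return out


def landmarks_from_iges(
    file_content: str, manifest: pd.DataFrame
) -> list[ArchModel]:
    """Assemble arch models from IGES points and an identity manifest.

    The manifest maps the 1-based order of point entities to identity; it
    must have columns ``seq, patient_id, arch, timepoint, tooth_fdi,
    landmark``.
    """
    points = parse_iges_points(file_content)
    required = {"seq", "patient_id", "arch", "timepoint", "tooth_fdi", "landmark"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValidationError(f"manifest is missing columns: {sorted(missing)}")
    rows = []
    for _, row in manifest.iterrows():
        seq = int(row["seq"])
        if not 1 <= seq <= len(points):
            raise ValidationError(
                f"manifest seq {seq} outside 1..{len(points)} extracted points"
            )
        _, xyz = points[seq - 1]
        rows.append(
            {
                "patient_id": str(row["patient_id"]),
                "arch": row["arch"],
                "timepoint": row["timepoint"],
                "tooth_fdi": int(row["tooth_fdi"]),
                "landmark": row["landmark"],
                "x_mm": xyz[0],
                "y_mm": xyz[1],
                "z_mm": xyz[2],
            }
        )
    return _models_from_frame(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Landmark CSV
# ---------------------------------------------------------------------------


def _models_from_frame(df: pd.DataFrame) -> list[ArchModel]:
    dup = df.duplicated(
        subset=["patient_id", "arch", "timepoint", "tooth_fdi", "landmark"]
    )
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            "duplicate landmark row for patient "
            f"{first['patient_id']} {first['arch']} {first['timepoint']} "
            f"tooth {first['tooth_fdi']} {first['landmark']}"
        )
    models = []
    for (pid, arch, tp), group in df.groupby(
        ["patient_id", "arch", "timepoint"], sort=False
    ):
        teeth: dict[int, ToothLandmarks] = {}
        for fdi, tooth_rows in group.groupby("tooth_fdi", sort=False):
            lm = {}
            for _, r in tooth_rows.iterrows():
                try:
                    kind = LandmarkKind(r["landmark"])
                except ValueError:
                    raise ValidationError(
                        f"unknown landmark name {r['landmark']!r} "
                        f"(tooth {fdi})"
                    )
                lm[kind] = np.array([r["x_mm"], r["y_mm"], r["z_mm"]], float)
            teeth[int(fdi)] = ToothLandmarks(int(fdi), lm)
        models.append(ArchModel(str(pid), arch, tp, teeth))
    return models


def read_landmarks_csv(file: str | Path) -> list[ArchModel]:
    """Read a landmark table into arch models.

    The table must have columns ``patient_id, arch, timepoint, tooth_fdi,
    landmark, x_mm, y_mm, z_mm``; every tooth must carry all five
    landmarks.
    """
    df = pd.read_csv(file, dtype={"patient_id": str})
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"landmark CSV is missing columns: {sorted(missing)}"
        )
    return _models_from_frame(df)


def write_landmarks_csv(models: Iterable[ArchModel], file: str | Path) -> None:
    """Write arch models as a landmark table (inverse of read_landmarks_csv)."""
    rows = []
    for model in models:
        for fdi, tooth in model.teeth.items():
            for kind in LANDMARK_ORDER:
                p = tooth[kind]
                rows.append(
                    {
                        "patient_id": model.patient_id,
                        "arch": model.arch,
                        "timepoint": model.timepoint,
                        "tooth_fdi": fdi,
                        "landmark": kind.value,
                        "x_mm": p[0],
                        "y_mm": p[1],
                        "z_mm": p[2],
                    }
                )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(file, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_ROT_COLUMNS = [
    f"rot_{k.value}_{ax}" for k in LANDMARK_ORDER for ax in ("x", "y", "z")
]

MEASURES_COLUMNS = [
    "tooth_fdi",
    "rotation_deg",
    "inclination_deg",
    "angulation_deg",
    *_ROT_COLUMNS,
]
DELTAS_COLUMNS = [
    "tooth_fdi",
    "d_rotation_deg",
    "d_inclination_deg",
    "d_angulation_deg",
]
STATS_COLUMNS = [
    "label",
    "n",
    "mean_diff_deg",
    "sd_deg",
    "ci_low_deg",
    "ci_high_deg",
    "loa_low_deg",
    "loa_high_deg",
    "t_stat",
    "p_value",
    "dahlberg_deg",
]


def _measures_row(m) -> dict:
    row = {
        "tooth_fdi": m.tooth_id,
        "rotation_deg": m.rotation_deg,
        "inclination_deg": m.inclination_deg,
        "angulation_deg": m.angulation_deg,
    }
    for kind in LANDMARK_ORDER:
        p = m.rotated_coords[kind]
        for ax, v in zip("xyz", p):
            row[f"rot_{kind.value}_{ax}"] = v
    return row


def _record_kind(rec) -> str:
    if hasattr(rec, "rotated_coords"):
        return "measures"
    if hasattr(rec, "d_rotation_deg"):
        return "deltas"
    return "stats"


def write_tables(records: Sequence, file: str | Path, kind: str | None = None) -> None:
    """Write measurement, delta or agreement records as a CSV table.

    ``kind`` (``measures`` | ``deltas`` | ``stats``) selects the schema when
    ``records`` is empty; otherwise it is inferred from the first record.
    Stats records are ``(label, AgreementStats)`` pairs.  Angles and
    coordinates are written with six decimal places.
    """
    records = list(records)
    if kind is None:
        if not records:
            raise ValidationError("empty record list requires an explicit kind")
        kind = _record_kind(records[0][1] if isinstance(records[0], tuple) else records[0])
    if kind == "measures":
        df = pd.DataFrame([_measures_row(m) for m in records], columns=MEASURES_COLUMNS)
    elif kind == "deltas":
        df = pd.DataFrame(
            [
                {
                    "tooth_fdi": d.tooth_id,
                    "d_rotation_deg": d.d_rotation_deg,
                    "d_inclination_deg": d.d_inclination_deg,
                    "d_angulation_deg": d.d_angulation_deg,
                }
                for d in records
            ],
            columns=DELTAS_COLUMNS,
        )
    elif kind == "stats":
        rows = []
        for label, s in records:
            rows.append(
                {
                    "label": label,
                    "n": s.n,
                    "mean_diff_deg": s.mean_diff,
                    "sd_deg": s.sd_diff,
                    "ci_low_deg": s.ci_low,
                    "ci_high_deg": s.ci_high,
                    "loa_low_deg": s.loa_low,
                    "loa_high_deg": s.loa_high,
                    "t_stat": s.t_stat,
                    "p_value": s.p_value,
                    "dahlberg_deg": s.dahlberg,
                }
            )
        df = pd.DataFrame(rows, columns=STATS_COLUMNS)
    else:
        raise ValidationError(f"unknown table kind {kind!r}")
    df.to_csv(file, index=False, float_format="%.6f")
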
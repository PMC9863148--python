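"""Membrane-array geometry, annotation and cohort screening.

An :class:`ArrayLayout` describes one membrane design: a lattice of spot
blocks separated by alleyways, with every lattice position annotated by the
analyte printed there and its role (analyte in duplicate, reference anchor,
negative control, or empty).  Every downstream stage — grid inference,
densitometry, detection and differential expression — consumes this object.

Layouts are stored as a JSON file (geometry scalars) plus a TSV sidecar
(per-position annotation); see :func:`load_layout` / :func:`save_layout`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "ArrayLayout",
    "CohortRecord",
    "LayoutFormatError",
    "LayoutValidationError",
    "load_layout",
    "save_layout",
    "validate_layout",
    "screen_cohort",
    "load_cohort",
    "ROLES",
]

ROLES = ("analyte", "reference", "negative", "empty")

#: eGFR threshold (mL/min per 1.73 m^2) below which a subject is CKD.
EGFR_CKD_THRESHOLD = 60.0
#: Albumin/creatinine ratio threshold (mg/mmol) at or above which a subject is CKD.
ACR_CKD_THRESHOLD = 3.0


class LayoutFormatError(ValueError):
    """Raised when a layout file cannot be parsed."""


class LayoutValidationError(ValueError):
    """Raised when a layout violates its structural invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid layout:\n" + "\n".join(self.violations))


@dataclass(frozen=True)
class ArrayLayout:
    """Geometry and annotation of one membrane-array design.

    Parameters
    ----------
    name
        Free-text identifier of the design.
    n_block_rows, n_block_cols
        Number of spot blocks along each axis.
    rows_per_block, cols_per_block
        Spot lattice dimensions within one block.
    pitch
        Centre-to-centre spot distance in pixels.
    alley_row, alley_col
        Extra gap between adjacent blocks, expressed in pitch units
        (0 means blocks abut seamlessly).
    spot_radius
        Radius in pixels of the circular quantification aperture; must be
        smaller than half the pitch so apertures never overlap.
    positions
        One tuple ``(block_row, block_col, row, col, analyte, role)`` per
        printed spot; ``role`` is one of :data:`ROLES`.
    """

    name: str
    n_block_rows: int
    n_block_cols: int
    rows_per_block: int
    cols_per_block: int
    pitch: float
    alley_row: float
    alley_col: float
    spot_radius: float
    positions: tuple[tuple[int, int, int, int, str, str], ...] = field(default=())

    # -- derived views -----------------------------------------------------
    def position_index(self, entry) -> tuple[int, int, int, int]:
        return tuple(entry[:4])

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def positions_by_role(self, role: str) -> list[tuple[int, int, int, int]]:
        return [p[:4] for p in self.positions if p[5] == role]

    def duplicate_groups(self) -> dict[str, list[tuple[int, int, int, int]]]:
        """Map each analyte name to the list of positions printing it."""
        groups: dict[str, list[tuple[int, int, int, int]]] = {}
        for br, bc, r, c, analyte, role in self.positions:
            if role == "analyte":
                groups.setdefault(analyte, []).append((br, bc, r, c))
        return groups

    @property
    def analytes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.positions:
            if p[5] == "analyte":
                seen.setdefault(p[4])
        return list(seen)

    def validate(self) -> list[str]:
        return validate_layout(self)

    def check_valid(self) -> "ArrayLayout":
        violations = validate_layout(self)
        if violations:
            raise LayoutValidationError(violations)
        return self


def validate_layout(layout: ArrayLayout) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    v: list[str] = []
    for fname in ("n_block_rows", "n_block_cols", "rows_per_block", "cols_per_block"):
        if getattr(layout, fname) < 1:
            v.append(f"{fname} must be a positive integer")
    if layout.pitch <= 0:
        v.append("pitch must be positive")
    if layout.alley_row < 0 or layout.alley_col < 0:
        v.append("alley_row/alley_col must be non-negative")
    if layout.spot_radius <= 0:
        v.append("spot_radius must be positive")
    elif layout.pitch > 0 and not layout.spot_radius < layout.pitch / 2:
        v.append("spot_radius must be < pitch/2")

    seen: set[tuple[int, int, int, int]] = set()
    n_analyte = 0
    for br, bc, r, c, analyte, role in layout.positions:
        key = (br, bc, r, c)
        if key in seen:
            v.append(f"duplicate position index {key}")
        seen.add(key)
        if role not in ROLES:
            v.append(f"position {key}: unknown role {role!r}")
        if not (0 <= br < layout.n_block_rows and 0 <= bc < layout.n_block_cols):
            v.append(f"position {key}: block index outside declared grid")
        if not (0 <= r < layout.rows_per_block and 0 <= c < layout.cols_per_block):
            v.append(f"position {key}: spot index outside declared block")
        if role == "analyte":
            n_analyte += 1

    groups = layout.duplicate_groups()
    if n_analyte and not groups:
        v.append("no analyte-role positions declared")
    sizes = {len(g) for g in groups.values()}
    if len(sizes) > 1:
        # duplicate groups must partition analyte spots into equal-size sets
        expected = min(sizes)
        for analyte, g in groups.items():
            if len(g) != expected:
                v.append(
                    f"analyte {analyte!r} has {len(g)} duplicate positions, "
                    f"expected {expected}"
                )
    return v


# ---------------------------------------------------------------------------
# serialization: JSON geometry + TSV annotation
# ---------------------------------------------------------------------------

_GEOMETRY_KEYS = (
    "name",
    "n_block_rows",
    "n_block_cols",
    "rows_per_block",
    "cols_per_block",
    "pitch",
    "alley_row",
    "alley_col",
    "spot_radius",
)

_TSV_COLUMNS = ["block_row", "block_col", "row", "col", "analyte", "role"]


def load_layout(path: str | Path) -> ArrayLayout:
    """Load and validate a layout from ``<path>.json`` + ``<path>.tsv``.

    ``path`` may point at either file (or at the stem); both must exist.
    Raises :class:`LayoutFormatError` on parse failure and
    :class:`LayoutValidationError` when invariants are violated.
    """
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in {".json", ".tsv"} else path
    json_path = stem.with_suffix(".json")
    tsv_path = stem.with_suffix(".tsv")
    if not json_path.exists():
        raise LayoutFormatError(f"layout geometry file not found: {json_path}")
    if not tsv_path.exists():
        raise LayoutFormatError(f"layout annotation file not found: {tsv_path}")

    try:
        geom = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise LayoutFormatError(f"{json_path}: invalid JSON at line {exc.lineno}") from exc
    missing = [k for k in _GEOMETRY_KEYS if k not in geom]
    if missing:
        raise LayoutFormatError(f"{json_path}: missing geometry fields {missing}")

    try:
        ann = pd.read_csv(tsv_path, sep="\t", dtype={"analyte": str, "role": str})
    except Exception as exc:  # pandas raises several parser error types
        raise LayoutFormatError(f"{tsv_path}: cannot parse TSV ({exc})") from exc
    missing_cols = [c for c in _TSV_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise LayoutFormatError(f"{tsv_path}: missing columns {missing_cols}")

    positions = tuple(
        (int(t.block_row), int(t.block_col), int(t.row), int(t.col),
         "" if pd.isna(t.analyte) else str(t.analyte), str(t.role))
        for t in ann.itertuples()
    )
    layout = ArrayLayout(
        name=str(geom["name"]),
        n_block_rows=int(geom["n_block_rows"]),
        n_block_cols=int(geom["n_block_cols"]),
        rows_per_block=int(geom["rows_per_block"]),
        cols_per_block=int(geom["cols_per_block"]),
        pitch=float(geom["pitch"]),
        alley_row=float(geom["alley_row"]),
        alley_col=float(geom["alley_col"]),
        spot_radius=float(geom["spot_radius"]),
        positions=positions,
    )
    return layout.check_valid()


def save_layout(layout: ArrayLayout, path: str | Path) -> None:
    """Write ``<path>.json`` + ``<path>.tsv``; inverse of :func:`load_layout`."""
    stem = Path(path)
    if stem.suffix in {".json", ".tsv"}:
        stem = stem.with_suffix("")
    geom = {k: getattr(layout, k) for k in _GEOMETRY_KEYS}
    stem.with_suffix(".json").write_text(json.dumps(geom, indent=2) + "\n")
    ann = pd.DataFrame(list(layout.positions), columns=_TSV_COLUMNS)
    ann.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRecord:
    """One study subject with the two eligibility measurements.

    ``egfr`` is in mL/min per 1.73 m^2 and ``acr`` (albumin/creatinine
    ratio) in mg/mmol.
    """

    subject_id: str
    age: float
    egfr: float
    acr: float
    gender: str  # "male" | "female"
    declared_group: str  # "ckd" | "control"


def _eligibility(egfr: float, acr: float) -> str:
    if egfr < 0 or acr < 0:
        raise ValueError(f"egfr and acr must be non-negative (got {egfr}, {acr})")
    if egfr < EGFR_CKD_THRESHOLD or acr >= ACR_CKD_THRESHOLD:
        return "ckd"
    return "control"


def screen_cohort(records: Iterable[CohortRecord]) -> list[str]:
    """Label each record ``ckd`` / ``control`` / ``ineligible_conflict``.

    A subject is CKD when eGFR < 60 mL/min per 1.73 m^2 *or* ACR >= 3.0
    mg/mmol; control when eGFR >= 60 *and* ACR < 3.0.  A record whose
    computed label contradicts its declared group is flagged
    ``ineligible_conflict``.
    """
    labels = []
    for rec in records:
        label = _eligibility(rec.egfr, rec.acr)
        if rec.declared_group and label != rec.declared_group:
            label = "ineligible_conflict"
        labels.append(label)
    return labels


def load_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV (subject_id, age, egfr, acr, gender, group[, cohort])."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "age", "egfr", "acr", "gender", "group"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutFormatError(f"{path}: cohort CSV missing columns {sorted(missing)}")
    return [
        CohortRecord(
            subject_id=str(t.subject_id),
            age=float(t.age),
            egfr=float(t.egfr),
            acr=float(t.acr),
            gender=str(t.gender),
            declared_group=str(t.group),
        )
        for t in df.itertuples()
    ]
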
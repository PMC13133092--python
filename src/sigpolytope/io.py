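"""Reading and writing circuitry tables, geometry tables, and hull meshes.

Two input dialects are supported:

* ``generic`` — canonical column names: ``id``, ``cancer_type``, optional
  metadata columns, and per-side columns prefixed ``sig_`` / ``int_``
  (``rho``, ``rho_adj_p``, ``tn_direction``, ``tn_wilcoxon_p``,
  ``{os,dss,dfi,pfi}_direction/_p/_chi2/_significant``, ``micro_score``,
  ``immune_class``).
* ``dataset_s1`` — a column map for supplementary-style atlas exports
  (documented in the README); values are renamed onto the generic
  schema before parsing.

All tables are TSV/CSV (delimiter inferred from the extension), UTF-8,
'.' decimal separator; numeric values are serialized at full precision
(`repr`) so write -> read round trips are bit-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    DomainError,
    IntegrityError,
    ParseError,
    SchemaError,
)
from .geometry import DualPolytope, HullSummary
from .records import (
    ENDPOINTS,
    CircuitryRecord,
    CircuitryTable,
    SideAnnotation,
    SurvivalAnnotation,
)
from .regimes import GeometryRecord

_META_COLUMNS = ("omic_layer", "metabolic_class", "pathway", "phenotypic_layer")

_SIDE_FIELDS = (
    ["rho", "rho_adj_p", "tn_direction", "tn_wilcoxon_p"]
    + [f"{e}_{part}" for e in ENDPOINTS for part in ("direction", "p", "chi2", "significant")]
    + ["micro_score", "immune_class"]
)

#: Column map for the dataset_s1 dialect (supplementary-style headers ->
#: generic schema).
DATASET_S1_COLUMN_MAP: dict[str, str] = {"Circuitry_ID": "id", "Cancer_Type": "cancer_type"}
for _side, _pfx in (("Sig", "sig"), ("Int", "int")):
    DATASET_S1_COLUMN_MAP.update(
        {
            f"{_side}_Spearman_Rho": f"{_pfx}_rho",
            f"{_side}_Spearman_AdjP": f"{_pfx}_rho_adj_p",
            f"{_side}_TvN_Direction": f"{_pfx}_tn_direction",
            f"{_side}_TvN_WilcoxonP": f"{_pfx}_tn_wilcoxon_p",
            f"{_side}_TME_Score": f"{_pfx}_micro_score",
            f"{_side}_Immune_Class": f"{_pfx}_immune_class",
        }
    )
    for _e in ENDPOINTS:
        E = _e.upper()
        DATASET_S1_COLUMN_MAP.update(
            {
                f"{_side}_{E}_Cox_Direction": f"{_pfx}_{_e}_direction",
                f"{_side}_{E}_P": f"{_pfx}_{_e}_p",
                f"{_side}_{E}_LogRank_Chi2": f"{_pfx}_{_e}_chi2",
                f"{_side}_{E}_Significant": f"{_pfx}_{_e}_significant",
            }
        )
DATASET_S1_COLUMN_MAP.update(
    {
        "Omic_Layer": "omic_layer",
        "Metabolic_Class": "metabolic_class",
        "Pathway": "pathway",
        "Phenotypic_Layer": "phenotypic_layer",
    }
)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _parse_bool(value, row: int, col: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ParseError(f"row {row}, column {col!r}: cannot parse boolean from {value!r}")


def _parse_float(value, row: int, col: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        raise ParseError(f"row {row}, column {col!r}: missing numeric value")
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"row {row}, column {col!r}: cannot parse number from {value!r}"
        ) from exc


def _side_from_row(row: pd.Series, prefix: str, row_num: int) -> SideAnnotation:
    get = lambda f: row[f"{prefix}_{f}"]  # noqa: E731
    survival = {}
    for e in ENDPOINTS:
        survival[e] = SurvivalAnnotation(
            direction=str(get(f"{e}_direction")),
            p=_parse_float(get(f"{e}_p"), row_num, f"{prefix}_{e}_p"),
            chi2=_parse_float(get(f"{e}_chi2"), row_num, f"{prefix}_{e}_chi2"),
            significant=_parse_bool(get(f"{e}_significant"), row_num, f"{prefix}_{e}_significant"),
        )
    return SideAnnotation(
        rho=_parse_float(get("rho"), row_num, f"{prefix}_rho"),
        rho_adj_p=_parse_float(get("rho_adj_p"), row_num, f"{prefix}_rho_adj_p"),
        tn_direction=str(get("tn_direction")),
        tn_wilcoxon_p=_parse_float(get("tn_wilcoxon_p"), row_num, f"{prefix}_tn_wilcoxon_p"),
        survival=survival,
        micro_score=_parse_float(get("micro_score"), row_num, f"{prefix}_micro_score"),
        immune_class=str(get("immune_class")),
    )


def read_circuitry_table(path, dialect: str = "generic") -> CircuitryTable:
    """Read a circuitry annotation table from TSV/CSV.

    Missing mandatory columns raise :class:`SchemaError` naming the
    column; duplicate ids raise :class:`IntegrityError`; unparseable
    cells raise :class:`ParseError` with row/column coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file does not exist: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=object)
    if dialect == "dataset_s1":
        df = df.rename(columns=DATASET_S1_COLUMN_MAP)
    elif dialect != "generic":
        raise SchemaError(f"unknown dialect {dialect!r}")
    mandatory = ["id", "cancer_type"] + [
        f"{p}_{f}" for p in ("sig", "int") for f in _SIDE_FIELDS
    ]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        cid = str(row["id"])
        if cid in seen:
            raise IntegrityError(f"duplicate circuitry id {cid!r} at row {i}")
        seen.add(cid)
        meta = {c: (str(row[c]) if c in df.columns and pd.notna(row[c]) else "") for c in _META_COLUMNS}
        records.append(
            CircuitryRecord(
                id=cid,
                cancer_type=str(row["cancer_type"]),
                sig=_side_from_row(row, "sig", int(i)),
                int_=_side_from_row(row, "int", int(i)),
                **meta,
            )
        )
    return CircuitryTable(records=records, source_path=str(path), dialect=dialect)


def write_circuitry_table(table: CircuitryTable, path) -> None:
    """Write a circuitry table in the generic dialect (full precision)."""
    rows = []
    for rec in table:
        row: dict = {"id": rec.id, "cancer_type": rec.cancer_type}
        for c in _META_COLUMNS:
            row[c] = getattr(rec, c)
        for prefix, side in (("sig", rec.sig), ("int", rec.int_)):
            row[f"{prefix}_rho"] = repr(side.rho)
            row[f"{prefix}_rho_adj_p"] = repr(side.rho_adj_p)
            row[f"{prefix}_tn_direction"] = side.tn_direction
            row[f"{prefix}_tn_wilcoxon_p"] = repr(side.tn_wilcoxon_p)
            for e in ENDPOINTS:
                s = side.survival[e]
                row[f"{prefix}_{e}_direction"] = s.direction
                row[f"{prefix}_{e}_p"] = repr(s.p)
                row[f"{prefix}_{e}_chi2"] = repr(s.chi2)
                row[f"{prefix}_{e}_significant"] = str(s.significant)
            row[f"{prefix}_micro_score"] = repr(side.micro_score)
            row[f"{prefix}_immune_class"] = side.immune_class
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


_GEOMETRY_NUMERIC = (
    "dbary",
    "vol_sig",
    "vol_int",
    "asym_ratio",
    "asym_symmetrized",
    "anisotropy_sig",
    "anisotropy_int",
)
_GEOMETRY_LABELS = ("distance_regime", "volume_class", "joint_phenotype", "concordance_class")


def write_geometry_table(records: list[GeometryRecord], path) -> None:
    """Write per-circuitry descriptors and labels as TSV (full precision)."""
    if not records:
        raise DomainError("cannot write an empty geometry table")
    rows = []
    for r in records:
        row: dict = {"id": r.id, "cancer_type": r.cancer_type}
        for f in _GEOMETRY_NUMERIC:
            row[f] = repr(getattr(r, f))
        for f in _GEOMETRY_LABELS:
            row[f] = getattr(r, f)
        row["degenerate"] = str(r.degenerate)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_geometry_table(path) -> list[GeometryRecord]:
    """Read back a geometry table written by :func:`write_geometry_table`."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=object)
    records = []
    for i, row in df.iterrows():
        records.append(
            GeometryRecord(
                id=str(row["id"]),
                cancer_type=str(row["cancer_type"]),
                **{f: _parse_float(row[f], int(i), f) for f in _GEOMETRY_NUMERIC},
                **{f: str(row[f]) for f in _GEOMETRY_LABELS},
                degenerate=_parse_bool(row["degenerate"], int(i), "degenerate"),
            )
        )
    return records


def _write_off(vertices: np.ndarray, faces: np.ndarray, fh) -> None:
    fh.write("OFF\n")
    fh.write(f"{len(vertices)} {len(faces)} 0\n")
    for v in vertices:
        fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
    for f in faces:
        fh.write("3 " + " ".join(str(int(j)) for j in f) + "\n")


def _write_ply(vertices: np.ndarray, faces: np.ndarray, fh, comment: str) -> None:
    fh.write("ply\nformat ascii 1.0\n")
    fh.write(f"comment {comment}\n")
    fh.write(f"element vertex {len(vertices)}\n")
    fh.write("property float x\nproperty float y\nproperty float z\n")
    fh.write(f"element face {len(faces)}\n")
    fh.write("property list uchar int vertex_indices\nend_header\n")
    for v in vertices:
        fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
    for f in faces:
        fh.write("3 " + " ".join(str(int(j)) for j in f) + "\n")


def write_hull_mesh(hull: HullSummary, path, format: str = "OFF", comment: str = "hull") -> None:
    """Write a single convex hull as an OFF or PLY mesh file."""
    if format not in ("OFF", "PLY"):
        raise DomainError(f"unsupported mesh format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if format == "OFF":
            _write_off(hull.vertices, hull.facets, fh)
        else:
            _write_ply(hull.vertices, hull.facets, fh, comment)


def export_hull_mesh(polytope: DualPolytope, path, format: str = "OFF") -> None:
    """Export the two hulls of a circuitry as mesh files.

    Writes ``<stem>_sig.<ext>`` and ``<stem>_int.<ext>`` next to
    ``path``; both hulls must be nondegenerate 3-D hulls.
    """
    if format not in ("OFF", "PLY"):
        raise DomainError(f"unsupported mesh format {format!r}")
    if polytope.hull_sig is None or polytope.hull_int is None or polytope.degenerate:
        raise DegenerateGeometryError(
            f"circuitry {polytope.id!r}: cannot export degenerate hull(s)"
        )
    path = Path(path)
    ext = format.lower()
    for name, hull in (("sig", polytope.hull_sig), ("int", polytope.hull_int)):
        out = path.with_name(f"{path.stem}_{name}.{ext}")
        with open(out, "w", encoding="utf-8") as fh:
            if format == "OFF":
                _write_off(hull.vertices, hull.facets, fh)
            else:
                _write_ply(hull.vertices, hull.facets, fh, f"{polytope.id} {name} hull")


def read_off_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse an OFF file back into (vertices, faces) arrays."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if lines[0] != "OFF":
        raise ParseError(f"{path}: not an OFF file")
    nv, nf, _ = (int(x) for x in lines[1].split())
    verts = np.array([[float(x) for x in ln.split()] for ln in lines[2 : 2 + nv]])
    faces = np.array(
        [[int(x) for x in ln.split()[1:]] for ln in lines[2 + nv : 2 + nv + nf]], dtype=int
    )
    return verts, faces


def write_summary_json(path, summary: dict) -> None:
    """Write an atlas-level JSON summary (counts, thresholds, parameters)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
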
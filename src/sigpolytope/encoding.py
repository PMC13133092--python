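"""Latent encoding: annotations -> 18-dimensional latent vectors.

Each circuitry side is condensed into 18 named coordinates:

====================  =========================================================
coordinate            meaning
====================  =========================================================
rho                   Spearman correlation with the phenotypic attribute
rho_strength          transformed adjusted P of that correlation
tn_dir                tumor-vs-normal direction, signed (-1/0/+1)
tn_strength           -log10 Wilcoxon P of the tumor-normal comparison
{os,dss,dfi,pfi}_dir  Cox direction per endpoint, signed (+1 risk, -1 protective)
{..}_strength         transformed survival P per endpoint
{..}_chi2             raw log-rank chi-square per endpoint
micro_score           continuous microenvironment score
immune_code           immune class as a signed value (hot +1, cold -1, else 0)
====================  =========================================================

Non-significant survival endpoints contribute an exact (0, 0, 0) block so
that non-informative axes cannot deform the geometry.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ConsistencyError, DomainError, EncodingError
from .records import ENDPOINTS, CircuitryTable, SideAnnotation, SurvivalAnnotation, normalize_label

#: Fixed coordinate order of the latent vector.  Serialized vectors always
#: carry these names so coordinates can never be silently reordered.
COORD_NAMES: tuple[str, ...] = (
    "rho",
    "rho_strength",
    "tn_dir",
    "tn_strength",
    "os_dir",
    "os_strength",
    "os_chi2",
    "dss_dir",
    "dss_strength",
    "dss_chi2",
    "dfi_dir",
    "dfi_strength",
    "dfi_chi2",
    "pfi_dir",
    "pfi_strength",
    "pfi_chi2",
    "micro_score",
    "immune_code",
)

N_LATENT = len(COORD_NAMES)  # 18

#: Coordinate groups, used by the axis-ablation robustness analysis.
AXIS_GROUPS: dict[str, tuple[str, ...]] = {
    "correlation": ("rho", "rho_strength"),
    "tumor_normal": ("tn_dir", "tn_strength"),
    "survival": tuple(
        f"{e}_{part}" for e in ENDPOINTS for part in ("dir", "strength", "chi2")
    ),
    "microenvironment": ("micro_score",),
    "immune": ("immune_code",),
}

_POSITIVE_LABELS = frozenset({"up", "risk"})
_NEGATIVE_LABELS = frozenset({"down", "protective"})


def encode_direction(label: str) -> float:
    """Map a categorical direction to a signed value.

    ``up``/``risk`` -> +1, ``down``/``protective`` -> -1, ``ns`` -> 0.
    """
    lab = normalize_label(label)
    if lab in _POSITIVE_LABELS:
        return 1.0
    if lab in _NEGATIVE_LABELS:
        return -1.0
    if lab == "ns":
        return 0.0
    raise EncodingError(f"unknown direction label {label!r}")


def encode_strength(p: float, transform: str = "neglog10", cap: float = 300.0) -> float:
    """Transform a P value into a nonnegative strength coordinate.

    With ``transform="neglog10"`` returns ``min(-log10(p), cap)``; the cap
    keeps underflowing P values finite.  ``transform="raw"`` passes ``p``
    through unchanged.
    """
    if not (0.0 < p <= 1.0):
        raise DomainError(f"p must lie in (0, 1], got {p}")
    if transform == "raw":
        return float(p)
    if transform == "neglog10":
        return float(min(-math.log10(p), cap))
    raise DomainError(f"unknown p-value transform {transform!r}")


def encode_survival_block(
    endpoint: SurvivalAnnotation, transform: str = "neglog10", cap: float = 300.0
) -> tuple[float, float, float]:
    """Encode one survival endpoint as (direction, strength, chi2).

    A non-significant endpoint is exactly (0, 0, 0) regardless of its
    stored direction/P/chi2, so uninformative axes carry no geometry.
    """
    if not endpoint.significant:
        return (0.0, 0.0, 0.0)
    if endpoint.direction == "ns":
        raise ConsistencyError("significant endpoint cannot have direction 'ns'")
    return (
        encode_direction(endpoint.direction),
        encode_strength(endpoint.p, transform, cap),
        float(endpoint.chi2),
    )


def encode_immune_class(label: str, mapping: dict[str, float] | None = None) -> float:
    """Map an immune class to a signed code.

    Default polarity: hot +1, cold -1, excluded 0, intermediate 0.
    """
    if mapping is None:
        mapping = {"hot": 1.0, "cold": -1.0, "excluded": 0.0, "intermediate": 0.0}
    lab = normalize_label(label)
    try:
        return float(mapping[lab])
    except KeyError as exc:
        raise EncodingError(f"unknown immune class {label!r}") from exc


def build_latent_vector(
    side: SideAnnotation, config: PipelineConfig | None = None
) -> np.ndarray:
    """Assemble the 18-coordinate latent vector for one circuitry side."""
    cfg = config or PipelineConfig()
    tr, cap = cfg.pvalue_transform, cfg.strength_cap
    coords = [
        float(side.rho),
        encode_strength(side.rho_adj_p, tr, cap),
        encode_direction(side.tn_direction),
        encode_strength(side.tn_wilcoxon_p, tr, cap),
    ]
    for e in ENDPOINTS:
        coords.extend(encode_survival_block(side.survival[e], tr, cap))
    coords.append(float(side.micro_score))
    coords.append(encode_immune_class(side.immune_class, cfg.immune_code_map))
    vec = np.asarray(coords, dtype=float)
    assert vec.shape == (N_LATENT,)
    return vec


def build_latent_tensor(
    table: CircuitryTable, config: PipelineConfig | None = None
) -> tuple[np.ndarray, pd.MultiIndex]:
    """Stack all sides of all circuitries into a (2N x 18) latent tensor.

    Rows are ordered (circuitry, side) with side order (sig, int) within
    each circuitry; the returned MultiIndex maps row -> (id, side).
    """
    if len(table) == 0:
        raise DomainError("cannot build a latent tensor from an empty table")
    cfg = config or PipelineConfig()
    rows = []
    index = []
    for rec in table:
        rows.append(build_latent_vector(rec.sig, cfg))
        index.append((rec.id, "sig"))
        rows.append(build_latent_vector(rec.int_, cfg))
        index.append((rec.id, "int"))
    tensor = np.vstack(rows)
    mi = pd.MultiIndex.from_tuples(index, names=["id", "side"])
    return tensor, mi


def latent_frame(table: CircuitryTable, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Latent tensor as a DataFrame with named coordinates (for export)."""
    tensor, mi = build_latent_tensor(table, config)
    return pd.DataFrame(tensor, index=mi, columns=list(COORD_NAMES))
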
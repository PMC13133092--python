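"""Regime classification: distance regimes, volume classes, joint phenotypes,
and the per-circuitry concordance summary.

The barycenter distance is binned into four half-open regimes
(boundaries go to the upper bin):

* high concordance        dbary <  t1          (default t1 = 0.5)
* moderate discordance    t1 <= dbary < t2     (default t2 = 1.5)
* strong discordance      t2 <= dbary < t3     (default t3 = 2.5)
* extreme discordance     dbary >= t3

Hull volumes are tiered Low / Intermediate / High by data-driven
quantiles of a scalar size summary (default: geometric mean of the two
side volumes), and crossed with three symmetry states from the
symmetrized volume ratio, yielding nine mutually exclusive classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError, InsufficientDataError
from .records import ENDPOINTS, SideAnnotation
from .encoding import encode_direction, encode_immune_class

DISTANCE_REGIMES = (
    "high_concordance",
    "moderate_discordance",
    "strong_discordance",
    "extreme_discordance",
)

VOLUME_TIERS = ("Low", "Intermediate", "High")
SYMMETRY_STATES = ("Symmetric", "Mod asymmetric", "Strong asymmetric")

JOINT_PHENOTYPES = (
    "concordant_low_dim",
    "concordant_high_dim",
    "discordant_low_dim",
    "discordant_high_dim_asymmetric",
)

CONCORDANCE_CLASSES = ("Only Convergent", "Only Divergent", "Mixed", "Indeterminate")


def classify_distance_regime(
    dbary: float, thresholds: tuple[float, float, float] = (0.5, 1.5, 2.5)
) -> str:
    """Bin a barycenter distance into one of the four discordance regimes."""
    if dbary < 0:
        raise DomainError(f"dbary must be nonnegative, got {dbary}")
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ConfigError("distance thresholds must be strictly increasing")
    if dbary < t1:
        return "high_concordance"
    if dbary < t2:
        return "moderate_discordance"
    if dbary < t3:
        return "strong_discordance"
    return "extreme_discordance"


def volume_tier_thresholds(
    volumes, probs: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
) -> tuple[float, float]:
    """Empirical quantile cut points (type-7 interpolation) for volume tiers.

    Degenerate (zero or non-finite) volumes must be excluded by the
    caller; fewer than 3 usable values is an error.
    """
    v = np.asarray(list(volumes), dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 3:
        raise InsufficientDataError(
            f"need at least 3 positive finite volumes, got {v.size}"
        )
    q1, q2 = probs
    if not (0 < q1 <= q2 < 1):
        raise ConfigError("quantile probabilities must be ordered and in (0,1)")
    v1, v2 = np.quantile(v, [q1, q2], method="linear")
    return float(v1), float(v2)


def _volume_tier(size: float, tiers: tuple[float, float]) -> str:
    v1, v2 = tiers
    if size < v1:
        return "Low"
    if size < v2:
        return "Intermediate"
    return "High"


def _symmetry_state(sym_ratio: float, bands: tuple[float, float]) -> str:
    s1, s2 = bands
    if not (1.0 < s1 < s2):
        raise ConfigError("symmetry bands must satisfy 1 < s1 < s2")
    if sym_ratio <= s1:
        return "Symmetric"
    if sym_ratio <= s2:
        return "Mod asymmetric"
    return "Strong asymmetric"


def volume_size_scalar(vol_sig: float, vol_int: float, kind: str = "geometric_mean") -> float:
    """Scalar size summary of the two side volumes used for tiering."""
    if kind == "geometric_mean":
        return float(np.sqrt(vol_sig * vol_int))
    if kind == "max":
        return float(max(vol_sig, vol_int))
    if kind == "mean":
        return float((vol_sig + vol_int) / 2.0)
    raise ConfigError(f"unknown tier scalar {kind!r}")


def classify_volume_class(
    vol_sig: float,
    vol_int: float,
    tiers: tuple[float, float],
    sym_bands: tuple[float, float] = (1.5, 3.0),
    tier_scalar: str = "geometric_mean",
) -> str:
    """Assign one of the nine volume classes ('<Tier>/<Symmetry>').

    Degenerate inputs (either volume nonpositive or non-finite) fall in
    the Low tier with Symmetric state, since no ratio is defined.
    """
    degenerate = not (
        np.isfinite(vol_sig) and np.isfinite(vol_int) and vol_sig > 0 and vol_int > 0
    )
    if degenerate:
        return "Low/Symmetric"
    size = volume_size_scalar(vol_sig, vol_int, tier_scalar)
    r = vol_sig / vol_int
    sym = max(r, 1.0 / r)
    return f"{_volume_tier(size, tiers)}/{_symmetry_state(sym, sym_bands)}"


def joint_geometric_phenotype(regime: str, volume_class: str) -> str:
    """Collapse (distance regime, volume class) into one of four phenotypes.

    Concordant means the high-concordance regime; everything else is
    discordant.  The Intermediate tier maps to the high-dimensional arm
    when asymmetric and to the low-dimensional arm otherwise.
    """
    if regime not in DISTANCE_REGIMES:
        raise ConfigError(f"unknown distance regime {regime!r}")
    tier, _, symmetry = volume_class.partition("/")
    if tier not in VOLUME_TIERS or symmetry not in SYMMETRY_STATES:
        raise ConfigError(f"unknown volume class {volume_class!r}")
    concordant = regime == "high_concordance"
    if tier == "High":
        high_dim = True
    elif tier == "Low":
        high_dim = False
    else:
        high_dim = symmetry != "Symmetric"
    if concordant:
        return "concordant_high_dim" if high_dim else "concordant_low_dim"
    return "discordant_high_dim_asymmetric" if high_dim else "discordant_low_dim"


def _axis_signs(side: SideAnnotation) -> dict[str, float]:
    """Signed value per comparable annotated axis for one side."""
    signs: dict[str, float] = {
        "rho": float(np.sign(side.rho)),
        "tn": encode_direction(side.tn_direction),
        "micro": float(np.sign(side.micro_score)),
        "immune": encode_immune_class(side.immune_class),
    }
    for e in ENDPOINTS:
        s = side.survival[e]
        signs[f"surv_{e}"] = encode_direction(s.direction) if s.significant else 0.0
    return signs


def concordance_summary(sig: SideAnnotation, int_: SideAnnotation) -> str:
    """Sign-agreement summary across annotated axis families.

    Axes compared: phenotype-correlation sign, tumor-normal direction,
    each survival endpoint significant on both sides, microenvironment
    sign, and immune polarity.  Axes where either side is neutral (0)
    are excluded.  All comparable axes agreeing -> "Only Convergent";
    all disagreeing -> "Only Divergent"; otherwise "Mixed"; no
    comparable axis -> "Indeterminate".
    """
    s_signs = _axis_signs(sig)
    i_signs = _axis_signs(int_)
    agreements = disagreements = 0
    for axis, sv in s_signs.items():
        iv = i_signs[axis]
        if sv == 0.0 or iv == 0.0:
            continue
        if sv == iv:
            agreements += 1
        else:
            disagreements += 1
    if agreements == 0 and disagreements == 0:
        return "Indeterminate"
    if disagreements == 0:
        return "Only Convergent"
    if agreements == 0:
        return "Only Divergent"
    return "Mixed"


@dataclass
class GeometryRecord:
    """Descriptors plus categorical labels for one circuitry."""

    id: str
    cancer_type: str
    dbary: float
    vol_sig: float
    vol_int: float
    asym_ratio: float
    asym_symmetrized: float
    anisotropy_sig: float
    anisotropy_int: float
    distance_regime: str
    volume_class: str
    joint_phenotype: str
    concordance_class: str
    degenerate: bool = False
    metadata: dict = field(default_factory=dict)
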
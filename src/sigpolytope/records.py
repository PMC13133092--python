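"""Domain records: per-side annotations, circuitries, and the circuitry table.

A *circuitry* pairs a regulatory signature side (``sig``) with its
experimentally supported interaction side (``int``).  Each side carries
the summary statistics computed upstream against patient cohorts: a
Spearman correlation with a phenotypic attribute, tumor-versus-normal
differential direction, Cox/log-rank results for four survival
endpoints, a continuous microenvironment score, and a categorical
immune class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConsistencyError, DomainError, EncodingError, IntegrityError

#: Survival endpoints, in canonical order.
ENDPOINTS: tuple[str, ...] = ("os", "dss", "dfi", "pfi")

#: Canonical tumor-vs-normal direction labels (synonyms normalized on input).
TN_DIRECTIONS = frozenset({"up", "down", "ns"})
SURV_DIRECTIONS = frozenset({"risk", "protective", "ns"})
IMMUNE_CLASSES = frozenset({"hot", "cold", "excluded", "intermediate"})

#: Accepted synonyms for the neutral / non-significant state.
_NS_SYNONYMS = frozenset({"ns", "non-significant", "nonsignificant", "none", "neutral"})


def normalize_label(label: str) -> str:
    """Lower-case, strip, and collapse non-significant synonyms to ``ns``."""
    lab = str(label).strip().lower()
    return "ns" if lab in _NS_SYNONYMS else lab


@dataclass(frozen=True)
class SurvivalAnnotation:
    """One survival endpoint on one circuitry side.

    ``significant=False`` marks the endpoint as non-informative; its
    direction/strength/chi2 contributions are zeroed at encoding time so
    non-significant axes cannot deform the circuitry geometry.
    """

    direction: str  # "risk" | "protective" | "ns"
    p: float
    chi2: float
    significant: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", normalize_label(self.direction))
        if self.direction not in SURV_DIRECTIONS:
            raise EncodingError(f"unknown survival direction {self.direction!r}")
        if not (0.0 < self.p <= 1.0):
            raise DomainError(f"survival p must lie in (0, 1], got {self.p}")
        if self.chi2 < 0:
            raise DomainError(f"chi2 must be nonnegative, got {self.chi2}")
        if self.significant and self.direction == "ns":
            raise ConsistencyError(
                "endpoint flagged significant but direction is non-significant"
            )


@dataclass(frozen=True)
class SideAnnotation:
    """Full annotation block for one side (sig or int) of a circuitry."""

    rho: float
    rho_adj_p: float
    tn_direction: str  # "up" | "down" | "ns"
    tn_wilcoxon_p: float
    survival: dict[str, SurvivalAnnotation]
    micro_score: float
    immune_class: str

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise DomainError(f"rho must lie in [-1, 1], got {self.rho}")
        if not (0.0 < self.rho_adj_p <= 1.0):
            raise DomainError(f"adjusted p must lie in (0, 1], got {self.rho_adj_p}")
        object.__setattr__(self, "tn_direction", normalize_label(self.tn_direction))
        if self.tn_direction not in TN_DIRECTIONS:
            raise EncodingError(f"unknown tumor-normal direction {self.tn_direction!r}")
        if not (0.0 < self.tn_wilcoxon_p <= 1.0):
            raise DomainError(f"Wilcoxon p must lie in (0, 1], got {self.tn_wilcoxon_p}")
        missing = [e for e in ENDPOINTS if e not in self.survival]
        if missing:
            raise ConsistencyError(f"missing survival endpoints: {missing}")
        object.__setattr__(self, "immune_class", normalize_label(self.immune_class))
        if self.immune_class not in IMMUNE_CLASSES:
            raise EncodingError(f"unknown immune class {self.immune_class!r}")


@dataclass(frozen=True)
class CircuitryRecord:
    """One regulatory circuitry: identifier, stratification metadata, two sides."""

    id: str
    cancer_type: str
    sig: SideAnnotation
    int_: SideAnnotation
    omic_layer: str = ""
    metabolic_class: str = ""
    pathway: str = ""
    phenotypic_layer: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise IntegrityError("circuitry id must be non-empty")
        if not self.cancer_type:
            raise IntegrityError(
                f"circuitry {self.id!r}: cancer-type stratum label is required"
            )

    def side(self, which: str) -> SideAnnotation:
        if which == "sig":
            return self.sig
        if which == "int":
            return self.int_
        raise KeyError(f"unknown side {which!r}")


@dataclass
class CircuitryTable:
    """An ordered collection of circuitries plus provenance."""

    records: list[CircuitryRecord]
    source_path: str = ""
    dialect: str = "generic"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise IntegrityError(f"duplicate circuitry id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def strata(self) -> list[str]:
        return [r.cancer_type for r in self.records]
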
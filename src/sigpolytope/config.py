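"""Pipeline configuration.

All tunable parameters of the geometric pipeline live in a single
:class:`PipelineConfig` dataclass so that a run is fully specified by
(config, input table).  Defaults follow the published operating point of
the framework: distance-regime thresholds at 0.5 / 1.5 / 2.5 in the
shared PC1--PC3 space, tercile volume quantiles, and a -log10 transform
for every P-value-derived strength axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

from .errors import ConfigError

PValueTransform = Literal["neglog10", "raw"]
EntropyBase = Literal["natural", "base2"]
VolumeSpace = Literal["pca3", "latent18"]
TierScalar = Literal["geometric_mean", "max", "mean"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters governing encoding, embedding, geometry and classification.

    Parameters
    ----------
    alpha
        Proportionality constant for axis-aligned vertex perturbations:
        each latent coordinate ``x_i`` is perturbed by
        ``max(alpha * |x_i|, epsilon)``.  Rescales hull volumes
        monotonically; does not affect barycenter distances.
    epsilon
        Minimal perturbation safeguard (> 0) so that zero coordinates
        still span a nondegenerate cross-polytope.
    n_components
        Number of leading principal components defining the shared
        coordinate system for distances and visualization (default 3).
    distance_thresholds
        Increasing cut points (t1, t2, t3) binning the barycenter
        distance into the four discordance regimes.
    volume_quantiles
        Probabilities for the data-driven volume tier thresholds.
    symmetry_ratio_thresholds
        Bands (s1, s2) on the symmetrized volume ratio max(r, 1/r)
        separating Symmetric / Mod asymmetric / Strong asymmetric.
    n_permutations
        Replicates B for the stratified permutation null.
    seed
        Seed for every stochastic component (permutations, simulation).
    pvalue_transform
        "neglog10" (default) or "raw" for strength axes.
    strength_cap
        Ceiling for -log10(p) so that underflowing P values stay finite.
    entropy_log_base
        Logarithm base for Shannon entropies ("natural" or "base2").
    scale
        If False, standardization centers but does not divide by the
        column standard deviation (robustness variant).
    sd_ddof
        Delta degrees of freedom of the standardizing SD (1 = sample SD).
    volume_space
        "pca3": hull volumes of the projected 36-vertex clouds in the
        3-D embedding (default).  "latent18": closed-form cross-polytope
        volume in the full 18-dimensional latent space.
    tier_scalar
        Scalar size summary of (vol_sig, vol_int) used for tiering.
    """

    alpha: float = 1.0
    epsilon: float = 0.05
    n_components: int = 3
    distance_thresholds: tuple[float, float, float] = (0.5, 1.5, 2.5)
    volume_quantiles: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    symmetry_ratio_thresholds: tuple[float, float] = (1.5, 3.0)
    n_permutations: int = 500
    seed: int = 0
    pvalue_transform: PValueTransform = "neglog10"
    strength_cap: float = 300.0
    entropy_log_base: EntropyBase = "natural"
    scale: bool = True
    sd_ddof: int = 1
    volume_space: VolumeSpace = "pca3"
    tier_scalar: TierScalar = "geometric_mean"
    immune_code_map: dict = field(
        default_factory=lambda: {
            "hot": 1.0,
            "cold": -1.0,
            "excluded": 0.0,
            "intermediate": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        t1, t2, t3 = self.distance_thresholds
        if not (t1 < t2 < t3):
            raise ConfigError("distance_thresholds must be strictly increasing")
        q1, q2 = self.volume_quantiles
        if not (0 < q1 < 1 and 0 < q2 < 1 and q1 <= q2):
            raise ConfigError("volume_quantiles must be ordered probabilities in (0,1)")
        s1, s2 = self.symmetry_ratio_thresholds
        if not (1.0 < s1 < s2):
            raise ConfigError("symmetry_ratio_thresholds must satisfy 1 < s1 < s2")
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.pvalue_transform not in ("neglog10", "raw"):
            raise ConfigError(f"unknown pvalue_transform {self.pvalue_transform!r}")
        if self.entropy_log_base not in ("natural", "base2"):
            raise ConfigError(f"unknown entropy_log_base {self.entropy_log_base!r}")
        if self.volume_space not in ("pca3", "latent18"):
            raise ConfigError(f"unknown volume_space {self.volume_space!r}")
        if self.tier_scalar not in ("geometric_mean", "max", "mean"):
            raise ConfigError(f"unknown tier_scalar {self.tier_scalar!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distance_thresholds"] = list(self.distance_thresholds)
        d["volume_quantiles"] = list(self.volume_quantiles)
        d["symmetry_ratio_thresholds"] = list(self.symmetry_ratio_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("distance_thresholds", "volume_quantiles", "symmetry_ratio_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
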
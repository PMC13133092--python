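"""End-to-end pipeline: encode -> standardize -> PCA -> polytopes -> labels.

`run_pipeline` is the deterministic path from a circuitry table to one
:class:`GeometryRecord` per circuitry.  `embed_table` and
`pair_distances` expose the cheap inner path (no hulls) reused by the
permutation null and the ablation analysis, where only barycenter
distances and distance regimes are needed: because vertex clouds are
symmetric around their latent vector and projection is affine, the
projected barycenter equals the projected latent point, so dbary can be
computed without constructing hulls.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from .config import PipelineConfig
from .embedding import EmbeddingModel, fit_pca, standardize
from .encoding import build_latent_tensor
from .errors import DomainError
from .geometry import build_dual_polytope
from .records import CircuitryTable
from .regimes import (
    GeometryRecord,
    classify_distance_regime,
    classify_volume_class,
    concordance_summary,
    joint_geometric_phenotype,
    volume_tier_thresholds,
)

logger = logging.getLogger("sigpolytope")


def embed_table(
    table: CircuitryTable, config: PipelineConfig | None = None
) -> tuple[np.ndarray, EmbeddingModel]:
    """Build the 2N x 18 latent tensor and fit the joint embedding."""
    cfg = config or PipelineConfig()
    tensor, _ = build_latent_tensor(table, cfg)
    Z, means, scales = standardize(tensor, scale=cfg.scale, ddof=cfg.sd_ddof)
    model = fit_pca(Z, means=means, scales=scales, n_components_default=cfg.n_components)
    return tensor, model


def pair_distances(
    tensor: np.ndarray, model: EmbeddingModel, n_components: int = 3
) -> np.ndarray:
    """Barycenter distances for a (2N x 18) tensor with (sig, int) row pairs.

    Row 2i is the sig side and row 2i+1 the int side of circuitry i.
    """
    if tensor.shape[0] % 2 != 0:
        raise DomainError("tensor must contain an even number of rows (sig/int pairs)")
    scores = model.project(tensor, n_components=n_components)
    return np.linalg.norm(scores[0::2] - scores[1::2], axis=1)


def distances_and_regimes(
    tensor: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Standardize + PCA + project + dbary + regime, from a raw latent tensor."""
    cfg = config or PipelineConfig()
    Z, means, scales = standardize(tensor, scale=cfg.scale, ddof=cfg.sd_ddof)
    model = fit_pca(Z, means=means, scales=scales, n_components_default=cfg.n_components)
    d = pair_distances(tensor, model, n_components=cfg.n_components)
    regimes = [classify_distance_regime(x, cfg.distance_thresholds) for x in d]
    return d, regimes


def run_pipeline(
    config: PipelineConfig, table: CircuitryTable
) -> list[GeometryRecord]:
    """Execute the full geometric pipeline on a circuitry table.

    Deterministic given (config, table); returns one GeometryRecord per
    input circuitry, in input order.
    """
    if len(table) == 0:
        raise DomainError("pipeline input table is empty")
    t0 = time.perf_counter()
    tensor, model = embed_table(table, config)
    logger.info("stage=embed n=%d elapsed=%.3fs", len(table), time.perf_counter() - t0)

    t0 = time.perf_counter()
    polytopes = [build_dual_polytope(rec, model, config) for rec in table]
    logger.info("stage=geometry n=%d elapsed=%.3fs", len(polytopes), time.perf_counter() - t0)

    t0 = time.perf_counter()
    usable = [
        v
        for p in polytopes
        if not p.degenerate
        for v in (p.vol_sig, p.vol_int)
        if np.isfinite(v) and v > 0
    ]
    tiers = volume_tier_thresholds(usable, config.volume_quantiles)
    records: list[GeometryRecord] = []
    for rec, poly in zip(table, polytopes):
        regime = classify_distance_regime(poly.dbary, config.distance_thresholds)
        vol_class = classify_volume_class(
            poly.vol_sig,
            poly.vol_int,
            tiers,
            config.symmetry_ratio_thresholds,
            config.tier_scalar,
        )
        records.append(
            GeometryRecord(
                id=rec.id,
                cancer_type=rec.cancer_type,
                dbary=poly.dbary,
                vol_sig=poly.vol_sig,
                vol_int=poly.vol_int,
                asym_ratio=poly.asym_ratio,
                asym_symmetrized=poly.asym_symmetrized,
                anisotropy_sig=poly.anisotropy_sig,
                anisotropy_int=poly.anisotropy_int,
                distance_regime=regime,
                volume_class=vol_class,
                joint_phenotype=joint_geometric_phenotype(regime, vol_class),
                concordance_class=concordance_summary(rec.sig, rec.int_),
                degenerate=poly.degenerate,
                metadata={
                    "omic_layer": rec.omic_layer,
                    "metabolic_class": rec.metabolic_class,
                    "pathway": rec.pathway,
                    "phenotypic_layer": rec.phenotypic_layer,
                    "volume_tier_thresholds": tiers,
                },
            )
        )
    logger.info("stage=classify n=%d elapsed=%.3fs", len(records), time.perf_counter() - t0)
    return records
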
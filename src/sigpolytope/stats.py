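"""Atlas-level statistics: entropy, baseline benchmarks, permutation null,
and axis-ablation robustness.

The permutation null asks whether the observed discordance structure
could arise from random pairing of signature and interaction sides:
interaction latent vectors are reshuffled within cancer-type strata,
the shared embedding is recomputed per replicate, and global statistics
(mean dbary, proportion extreme-discordant, proportion
highly-concordant) are compared with their null draws through the
bias-corrected estimator p = (k + 1) / (B + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as _scipy_cosine
from scipy.stats import spearmanr

from .config import PipelineConfig
from .encoding import AXIS_GROUPS, COORD_NAMES, build_latent_tensor
from .errors import ConfigError, DomainError, InsufficientDataError
from .pipeline import distances_and_regimes
from .records import ENDPOINTS, CircuitryTable, SideAnnotation
from .encoding import encode_direction

PERMUTATION_STATISTICS = ("mean_dbary", "prop_extreme", "prop_high_concordance")


def shannon_entropy(proportions, base: str = "natural") -> float:
    """Shannon entropy of a probability vector, with 0*log(0) = 0."""
    p = np.asarray(list(proportions), dtype=float)
    if np.any(p < 0):
        raise DomainError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError(f"proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base == "base2":
        return h / math.log(2.0)
    if base == "natural":
        return h
    raise DomainError(f"unknown entropy base {base!r}")


def entropy_ordering(
    table: dict[str, "np.ndarray | list[float]"], base: str = "natural"
) -> list[tuple[str, float]]:
    """Order classes by decreasing Shannon entropy of their regime mix.

    Ties are broken lexicographically by class name.
    """
    entries = [(name, shannon_entropy(props, base)) for name, props in table.items()]
    return sorted(entries, key=lambda kv: (-kv[1], kv[0]))


@dataclass
class BaselineMetrics:
    """Simple vector-space discordance measures for one circuitry."""

    euclid18: float
    cosine_dist: float
    surv_mismatch: int
    immune_mismatch: int
    tn_mismatch: int
    micro_absdiff: float
    cosine_degenerate: bool = False


def baseline_metrics(
    sig_vec: np.ndarray,
    int_vec: np.ndarray,
    sig_ann: SideAnnotation,
    int_ann: SideAnnotation,
) -> BaselineMetrics:
    """Baseline discordance metrics from latent vectors plus annotations.

    ``euclid18``/``cosine_dist`` are computed on the vectors as given
    (pass standardized vectors for comparability with PC-space
    distances).  The survival mismatch counts only endpoints with a
    defined (significant) direction on both sides.  Cosine distance
    involving a zero vector is defined as 1 and flagged.
    """
    a = np.asarray(sig_vec, dtype=float)
    b = np.asarray(int_vec, dtype=float)
    euclid = float(np.linalg.norm(a - b))
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        cos_d, cos_degen = (0.0 if euclid == 0 else 1.0), True
    else:
        cos_d, cos_degen = float(_scipy_cosine(a, b)), False
    surv_mm = 0
    for e in ENDPOINTS:
        s, i = sig_ann.survival[e], int_ann.survival[e]
        if s.significant and i.significant:
            if encode_direction(s.direction) != encode_direction(i.direction):
                surv_mm += 1
    return BaselineMetrics(
        euclid18=euclid,
        cosine_dist=cos_d,
        surv_mismatch=surv_mm,
        immune_mismatch=int(sig_ann.immune_class != int_ann.immune_class),
        tn_mismatch=int(sig_ann.tn_direction != int_ann.tn_direction),
        micro_absdiff=float(abs(sig_ann.micro_score - int_ann.micro_score)),
        cosine_degenerate=cos_degen,
    )


def baseline_metrics_table(
    table: CircuitryTable, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-circuitry baseline metrics plus dbary, on standardized vectors."""
    from .embedding import standardize

    cfg = config or PipelineConfig()
    tensor, _ = build_latent_tensor(table, cfg)
    Z, _, _ = standardize(tensor, scale=cfg.scale, ddof=cfg.sd_ddof)
    d, _ = distances_and_regimes(tensor, cfg)
    rows = []
    for i, rec in enumerate(table):
        m = baseline_metrics(Z[2 * i], Z[2 * i + 1], rec.sig, rec.int_)
        rows.append(
            {
                "id": rec.id,
                "dbary": d[i],
                "euclid18": m.euclid18,
                "cosine_dist": m.cosine_dist,
                "surv_mismatch": m.surv_mismatch,
                "immune_mismatch": m.immune_mismatch,
                "tn_mismatch": m.tn_mismatch,
                "micro_absdiff": m.micro_absdiff,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def spearman_matrix(metrics: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix across discordance measures.

    Average ranks for ties; constant columns yield NaN entries rather
    than silent zeros.
    """
    if metrics.shape[0] < 3:
        raise InsufficientDataError("need at least 3 circuitries for correlations")
    cols = metrics.columns
    n = len(cols)
    out = np.full((n, n), np.nan)
    values = metrics.to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    for i in range(n):
        for j in range(i, n):
            if i == j:
                out[i, j] = 1.0 if not constant[i] else np.nan
                continue
            if constant[i] or constant[j]:
                continue
            rho = spearmanr(values[:, i], values[:, j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=cols, columns=cols)


@dataclass
class PermutationResult:
    """Outcome of the stratified permutation null."""

    B: int
    observed: dict[str, float]
    null_draws: np.ndarray  # (B x 3), columns ordered as PERMUTATION_STATISTICS
    p_values: dict[str, float]
    seed: int
    statistics: tuple[str, ...] = PERMUTATION_STATISTICS

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "statistics": list(self.statistics),
            "observed": self.observed,
            "p_values": self.p_values,
            "null_draws": self.null_draws.tolist(),
        }


def permutation_p_value(k: int, B: int) -> float:
    """Bias-corrected empirical p-value (k + 1) / (B + 1)."""
    if B < 1 or k < 0 or k > B:
        raise DomainError(f"invalid permutation counts k={k}, B={B}")
    return (k + 1) / (B + 1)


def _global_statistics(
    dbary: np.ndarray, regimes: list[str]
) -> tuple[float, float, float]:
    n = len(regimes)
    return (
        float(dbary.mean()),
        sum(r == "extreme_discordance" for r in regimes) / n,
        sum(r == "high_concordance" for r in regimes) / n,
    )


def _stratum_indices(strata: list[str]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for i, s in enumerate(strata):
        out.setdefault(s, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


def permutation_null(
    table: CircuitryTable, config: PipelineConfig | None = None
) -> PermutationResult:
    """Stratified permutation null for the global discordance structure.

    For each of B replicates the interaction-side latent vectors are
    reshuffled among circuitries within each cancer-type stratum
    (singleton strata stay fixed), the standardize + PCA + project +
    dbary + regime pipeline is recomputed in full, and the three global
    statistics are recorded.  All tests are upper-tailed; per-replicate
    RNG substreams are derived by counter from the seed so earlier
    replicates are unchanged when B grows.
    """
    cfg = config or PipelineConfig()
    B = cfg.n_permutations
    if B < 1:
        raise ConfigError("n_permutations must be >= 1")
    if len(table) < 2:
        raise InsufficientDataError("permutation null needs at least 2 circuitries")
    tensor, _ = build_latent_tensor(table, cfg)
    obs_d, obs_regimes = distances_and_regimes(tensor, cfg)
    observed = dict(zip(PERMUTATION_STATISTICS, _global_statistics(obs_d, obs_regimes)))
    strata_idx = _stratum_indices(table.strata())
    if all(len(v) < 2 for v in strata_idx.values()):
        raise InsufficientDataError("no stratum has >= 2 circuitries to permute")

    draws = np.empty((B, len(PERMUTATION_STATISTICS)))
    int_rows = tensor[1::2].copy()
    for b in range(B):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(b,))
        )
        perm_int = int_rows.copy()
        for idx in strata_idx.values():
            if len(idx) > 1:
                perm_int[idx] = int_rows[idx[rng.permutation(len(idx))]]
        perm_tensor = tensor.copy()
        perm_tensor[1::2] = perm_int
        d, regimes = distances_and_regimes(perm_tensor, cfg)
        draws[b] = _global_statistics(d, regimes)

    p_values = {
        stat: permutation_p_value(int(np.sum(draws[:, j] >= observed[stat])), B)
        for j, stat in enumerate(PERMUTATION_STATISTICS)
    }
    return PermutationResult(
        B=B, observed=observed, null_draws=draws, p_values=p_values, seed=cfg.seed
    )


@dataclass
class AblationResult:
    """Robustness of the geometry to removing an axis group / rescaling."""

    drop: str
    scale: bool
    spearman_vs_reference: float
    regime_agreement: float


def axis_ablation(
    table: CircuitryTable,
    drop: str = "none",
    scale: bool = True,
    config: PipelineConfig | None = None,
) -> AblationResult:
    """Recompute dbary after removing an axis group or disabling scaling.

    Reports the Spearman correlation of the modified dbary against the
    reference run and the fraction of circuitries keeping their
    distance-regime label.
    """
    cfg = config or PipelineConfig()
    if drop not in ("none",) + tuple(AXIS_GROUPS):
        raise ConfigError(f"unknown axis group {drop!r}")
    tensor, _ = build_latent_tensor(table, cfg)
    ref_d, ref_regimes = distances_and_regimes(tensor, cfg)

    if drop == "none":
        reduced = tensor
    else:
        keep = [i for i, c in enumerate(COORD_NAMES) if c not in AXIS_GROUPS[drop]]
        if not keep:
            raise ConfigError("cannot drop every latent axis")
        reduced = tensor[:, keep]
    mod_cfg = (
        cfg
        if scale == cfg.scale
        else PipelineConfig.from_dict({**cfg.to_dict(), "scale": scale})
    )
    mod_d, mod_regimes = distances_and_regimes(reduced, mod_cfg)

    if np.std(ref_d) == 0 or np.std(mod_d) == 0:
        rho = float("nan")
    else:
        rho = float(spearmanr(ref_d, mod_d).statistic)
    agreement = float(np.mean([a == b for a, b in zip(ref_regimes, mod_regimes)]))
    return AblationResult(
        drop=drop, scale=scale, spearman_vs_reference=rho, regime_agreement=agreement
    )
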
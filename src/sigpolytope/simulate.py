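"""Synthetic circuitry atlas generator.

Emulates the statistical shape of a per-circuitry annotation table:
signed tumor-normal and survival directions, positive strengths on a
-log10 P scale, log-rank chi-square statistics, a continuous
microenvironment score, a categorical immune class, and cancer-type
strata — with a controllable mixture of concordant and progressively
discordant sig/int pairs.

Each circuitry draws a latent orientation realized by the sig side.
The int side re-realizes it per mixture component: concordant pairs
copy the orientation with small jitter, while discordant pairs flip a
component-specific set of polar axes (correlation sign, tumor-normal
direction, significant survival directions, microenvironment sign,
immune polarity) and diverge in magnitude along the continuous axes.
Because barycenter distances live in the atlas's own standardized PCA
space, the generator calibrates the continuous-axis divergence of each
discordant pair against that embedding: every discordant circuitry is
assigned a target separation inside its component's distance band, and
a per-circuitry scale factor on the continuous displacement is solved
in closed form under the current embedding, iterating the
embed-then-solve step to a fixed point.  This yields mixture components
whose realized separations sit inside the intended regime bands rather
than merely being ordered.

Ground-truth component labels are returned separately so pipeline code
can never consume them accidentally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .embedding import fit_pca, standardize
from .encoding import COORD_NAMES, build_latent_tensor, build_latent_vector
from .errors import ConfigError
from .records import (
    ENDPOINTS,
    CircuitryRecord,
    CircuitryTable,
    SideAnnotation,
    SurvivalAnnotation,
)

MIXTURE_COMPONENTS = (
    "concordant",
    "moderately_discordant",
    "strongly_discordant",
    "extremely_discordant",
)

#: Per-component generator parameters.
#:
#: ``n_flips``            number of polar axes flipped on the int side
#:                        (-1 = every available axis)
#: ``jitter_sd``          SD of multiplicative log-scale jitter on strengths
#: ``strength_boost``     int-side magnitude inflation before calibration
#: ``min_sig_endpoints``  forced minimum of significant survival endpoints
#: ``force_tn``           force a directional tumor-normal axis
#: ``min_abs_rho``        magnitude floor on the correlation coordinate
#: ``min_abs_micro``      magnitude floor on the microenvironment score
#: ``target_band``        separation band (in shared PC1-PC3 units) the
#:                        calibration steers this component into; None
#:                        disables calibration (concordant pairs stay tight
#:                        by construction)
DEFAULT_EFFECT_SCALES: dict[str, dict] = {
    "concordant": {
        "n_flips": 0, "jitter_sd": 0.08, "strength_boost": 1.0,
        "min_sig_endpoints": 0, "force_tn": 0, "min_abs_rho": 0.0,
        "min_abs_micro": 0.0, "target_band": None,
    },
    "moderately_discordant": {
        "n_flips": 1, "jitter_sd": 0.20, "strength_boost": 1.2,
        "min_sig_endpoints": 1, "force_tn": 1, "min_abs_rho": 0.2,
        "min_abs_micro": 0.0, "target_band": (0.75, 1.30),
    },
    "strongly_discordant": {
        "n_flips": 2, "jitter_sd": 0.25, "strength_boost": 1.4,
        "min_sig_endpoints": 2, "force_tn": 1, "min_abs_rho": 0.3,
        "min_abs_micro": 0.4, "target_band": (1.80, 2.25),
    },
    "extremely_discordant": {
        "n_flips": -1, "jitter_sd": 0.35, "strength_boost": 2.0,
        "min_sig_endpoints": 3, "force_tn": 1, "min_abs_rho": 0.3,
        "min_abs_micro": 0.8, "target_band": (2.95, 5.5),
    },
}

#: Calibration loop iterations (embedding refit + closed-form re-solve).
_CALIBRATION_ITERATIONS = 5
#: Cap on the continuous-displacement scale factor, to keep magnitudes sane.
_MAX_SCALE = 12.0
_STRENGTH_CAP = 300.0

_DIR_COORDS = {"tn_dir", "os_dir", "dss_dir", "dfi_dir", "pfi_dir", "immune_code"}
_SIGN_IDX = np.array([i for i, c in enumerate(COORD_NAMES) if c in _DIR_COORDS])


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic atlas.

    The default mixture follows the published prevalence of the four
    discordance regimes (5.6% / 21.6% / 20.9% / 51.9%); the default
    survival-significance rate of 0.5 gives both informative and zeroed
    endpoint blocks in realistic proportion.
    """

    n_circuitries: int = 1000
    n_strata: int = 8
    mixture: tuple[float, float, float, float] = (0.056, 0.216, 0.209, 0.519)
    survival_significance_rate: float = 0.5
    immune_distribution: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    effect_scales: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_SCALES.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_circuitries < 1 or self.n_strata < 1:
            raise ConfigError("n_circuitries and n_strata must be positive")
        if abs(sum(self.mixture) - 1.0) > 1e-9 or any(m < 0 for m in self.mixture):
            raise ConfigError("mixture must be a 4-simplex")
        if abs(sum(self.immune_distribution) - 1.0) > 1e-9:
            raise ConfigError("immune_distribution must sum to 1")
        if not (0.0 <= self.survival_significance_rate <= 1.0):
            raise ConfigError("survival_significance_rate must lie in [0, 1]")
        for comp in MIXTURE_COMPONENTS:
            if comp not in self.effect_scales:
                raise ConfigError(f"effect_scales missing component {comp!r}")


_IMMUNE_LABELS = ("hot", "cold", "excluded", "intermediate")
_IMMUNE_FLIP = {"hot": "cold", "cold": "hot", "excluded": "excluded", "intermediate": "intermediate"}
_TN_FLIP = {"up": "down", "down": "up", "ns": "ns"}


def _jitter_p(p: float, sd: float, rng: np.random.Generator, boost: float = 1.0) -> float:
    """Multiplicative jitter of -log10(p), keeping p in (0, 1]."""
    strength = -math.log10(p) * boost * float(np.exp(rng.normal(0.0, sd)))
    return float(min(1.0, max(10.0 ** (-min(strength, _STRENGTH_CAP)), 1e-300)))


def _draw_sig_side(spec: SimulationSpec, rng: np.random.Generator) -> SideAnnotation:
    """Draw one annotation side with coherent latent factor structure.

    Real circuitry sides carry a net phenotypic orientation: risky sides
    tend to be up-regulated in tumors, share risk directions across
    survival endpoints, sit in pro-tumoral microenvironments and colder
    immune contexts.  Three per-side factors induce that correlation
    structure (and hence dominant principal axes in the pooled atlas):
    an orientation r = +/-1, a significance potency scaling all
    strengths, and a survival-significance propensity.
    """
    r = 1.0 if rng.random() < 0.5 else -1.0
    potency = float(np.exp(rng.normal(0.0, 0.5)))
    rate = spec.survival_significance_rate
    if 0.0 < rate < 1.0:
        propensity = float(rng.beta(2.0, 2.0 * (1.0 - rate) / rate))
    else:
        propensity = rate

    rho_sign = r if rng.random() < 0.7 else -r
    rho = float(rho_sign * rng.uniform(0.0, 0.6))
    rho_adj_p = float(10.0 ** -min(rng.uniform(0.3, 4.0) * potency, _STRENGTH_CAP))

    if rng.random() < 0.2:
        tn_dir, tn_p = "ns", float(rng.uniform(0.05, 1.0))
    else:
        aligned = rng.random() < 0.8
        tn_dir = ("up" if r > 0 else "down") if aligned else ("down" if r > 0 else "up")
        tn_p = float(10.0 ** -min(rng.uniform(1.3, 8.0) * potency, _STRENGTH_CAP))

    survival = {}
    for e in ENDPOINTS:
        if rng.random() < propensity:
            aligned = rng.random() < 0.85
            direction = ("risk" if r > 0 else "protective") if aligned else (
                "protective" if r > 0 else "risk"
            )
            survival[e] = SurvivalAnnotation(
                direction=direction,
                p=float(10.0 ** -min(rng.uniform(1.3, 5.0) * potency, _STRENGTH_CAP)),
                chi2=float((3.84 + rng.gamma(2.0, 3.0)) * potency),
                significant=True,
            )
        else:
            survival[e] = SurvivalAnnotation(
                direction="ns",
                p=float(rng.uniform(0.05, 1.0)),
                chi2=float(rng.uniform(0.0, 3.8)),
                significant=False,
            )

    micro = float(0.8 * r + rng.normal(0.0, 0.6))
    # immune polarity tied to orientation: risky sides skew cold
    if rng.random() < 0.5:
        immune = str(rng.choice(_IMMUNE_LABELS, p=spec.immune_distribution))
    else:
        immune = "cold" if r > 0 else "hot"

    return SideAnnotation(
        rho=rho,
        rho_adj_p=rho_adj_p,
        tn_direction=tn_dir,
        tn_wilcoxon_p=tn_p,
        survival=survival,
        micro_score=micro,
        immune_class=immune,
    )


def _enforce_availability(
    sig: SideAnnotation, params: dict, rng: np.random.Generator
) -> SideAnnotation:
    """Upgrade a sig side so its circuitry carries enough informative axes."""
    rho = sig.rho
    min_rho = params.get("min_abs_rho", 0.0)
    if abs(rho) < min_rho:
        rho = float(np.sign(rho) or 1.0) * float(rng.uniform(min_rho, 0.8))
    tn_dir, tn_p = sig.tn_direction, sig.tn_wilcoxon_p
    if params.get("force_tn", 0) and tn_dir == "ns":
        tn_dir = "up" if rng.random() < 0.5 else "down"
        tn_p = float(10.0 ** -rng.uniform(1.3, 8.0))
    survival = dict(sig.survival)
    n_sig = sum(survival[e].significant for e in ENDPOINTS)
    needed = int(params.get("min_sig_endpoints", 0)) - n_sig
    if needed > 0:
        candidates = [e for e in ENDPOINTS if not survival[e].significant]
        for e in rng.choice(candidates, size=needed, replace=False):
            survival[e] = SurvivalAnnotation(
                direction="risk" if rng.random() < 0.5 else "protective",
                p=float(10.0 ** -rng.uniform(1.3, 5.0)),
                chi2=float(3.84 + rng.gamma(2.0, 3.0)),
                significant=True,
            )
    micro = sig.micro_score
    min_micro = params.get("min_abs_micro", 0.0)
    if abs(micro) < min_micro:
        micro = float(np.sign(micro) or 1.0) * float(rng.uniform(min_micro, 2.5))
    return SideAnnotation(
        rho=rho,
        rho_adj_p=sig.rho_adj_p,
        tn_direction=tn_dir,
        tn_wilcoxon_p=tn_p,
        survival=survival,
        micro_score=micro,
        immune_class=sig.immune_class,
    )


def _available_flips(sig: SideAnnotation) -> list[str]:
    available = []
    if sig.rho != 0.0:
        available.append("rho")
    if sig.tn_direction != "ns":
        available.append("tn")
    for e in ENDPOINTS:
        if sig.survival[e].significant:
            available.append(f"surv_{e}")
    if sig.micro_score != 0.0:
        available.append("micro")
    if sig.immune_class in ("hot", "cold"):
        available.append("immune")
    return available


def _derive_int_side(
    sig: SideAnnotation,
    params: dict,
    rng: np.random.Generator,
    flips: set[str] | None = None,
) -> SideAnnotation:
    """Realize the int side: polar-axis flips plus magnitude divergence.

    ``flips`` overrides the sampled flip set (used when the calibration
    prunes direction flips that alone overshoot the target separation).
    """
    sd = params["jitter_sd"]
    boost = params.get("strength_boost", 1.0)

    available = _available_flips(sig)

    if flips is None:
        n_flips = int(params.get("n_flips", 0))
        if n_flips < 0 or n_flips >= len(available):
            flips = set(available)
        else:
            flips = (
                set(rng.choice(available, size=n_flips, replace=False))
                if n_flips
                else set()
            )

    rho = sig.rho * (-1.0 if "rho" in flips else 1.0)
    rho *= float(np.exp(rng.normal(0.0, sd)))
    rho = float(np.clip(rho, -1.0, 1.0))

    tn_dir = _TN_FLIP[sig.tn_direction] if "tn" in flips else sig.tn_direction

    survival = {}
    for e in ENDPOINTS:
        s = sig.survival[e]
        if s.significant:
            direction = (
                {"risk": "protective", "protective": "risk"}[s.direction]
                if f"surv_{e}" in flips
                else s.direction
            )
            survival[e] = SurvivalAnnotation(
                direction=direction,
                p=_jitter_p(s.p, sd, rng, boost),
                chi2=float(s.chi2 * boost * np.exp(rng.normal(0.0, sd))),
                significant=True,
            )
        else:
            survival[e] = SurvivalAnnotation(
                direction="ns",
                p=float(rng.uniform(0.05, 1.0)),
                chi2=float(rng.uniform(0.0, 3.8)),
                significant=False,
            )

    micro = sig.micro_score * (-1.0 if "micro" in flips else 1.0)
    micro = float(micro + rng.normal(0.0, sd))

    immune = _IMMUNE_FLIP[sig.immune_class] if "immune" in flips else sig.immune_class

    ann = SideAnnotation(
        rho=rho,
        rho_adj_p=_jitter_p(sig.rho_adj_p, sd, rng),
        tn_direction=tn_dir,
        tn_wilcoxon_p=_jitter_p(sig.tn_wilcoxon_p, sd, rng) if tn_dir != "ns" else sig.tn_wilcoxon_p,
        survival=survival,
        micro_score=micro,
        immune_class=immune,
    )
    return ann, set(flips)


def _scalable_mask(sig: SideAnnotation) -> np.ndarray:
    """Continuous coordinates on which divergence can be rescaled.

    Directions and the immune code are discrete; strengths of
    non-significant blocks are either zeroed at encoding (survival) or
    tied to a non-directional label (tumor-normal), so scaling them
    would be meaningless or inconsistent.
    """
    mask = np.ones(len(COORD_NAMES), dtype=bool)
    mask[_SIGN_IDX] = False
    names = {c: i for i, c in enumerate(COORD_NAMES)}
    if sig.tn_direction == "ns":
        mask[names["tn_strength"]] = False
    for e in ENDPOINTS:
        if not sig.survival[e].significant:
            mask[names[f"{e}_strength"]] = False
            mask[names[f"{e}_chi2"]] = False
    return mask


def _annotation_from_latent(
    latent: np.ndarray, template: SideAnnotation
) -> SideAnnotation:
    """Rebuild an int-side annotation from adjusted latent coordinates.

    Categorical labels (directions, immune class, significance flags)
    come from the template; continuous magnitudes come from the latent
    vector, mapped back to the annotation scale (strength -> P value).
    """
    names = {c: i for i, c in enumerate(COORD_NAMES)}

    def p_from_strength(s: float) -> float:
        s = float(min(max(s, 0.0), _STRENGTH_CAP))
        return float(max(10.0 ** (-s), 1e-300)) if s > 0 else 1.0

    survival = {}
    for e in ENDPOINTS:
        t = template.survival[e]
        if t.significant:
            survival[e] = SurvivalAnnotation(
                direction=t.direction,
                p=p_from_strength(latent[names[f"{e}_strength"]]),
                chi2=float(max(latent[names[f"{e}_chi2"]], 0.0)),
                significant=True,
            )
        else:
            survival[e] = t
    return SideAnnotation(
        rho=float(np.clip(latent[names["rho"]], -1.0, 1.0)),
        rho_adj_p=p_from_strength(latent[names["rho_strength"]]),
        tn_direction=template.tn_direction,
        tn_wilcoxon_p=(
            p_from_strength(latent[names["tn_strength"]])
            if template.tn_direction != "ns"
            else template.tn_wilcoxon_p
        ),
        survival=survival,
        micro_score=float(latent[names["micro_score"]]),
        immune_class=template.immune_class,
    )


def _coordinate_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Domain bounds per latent coordinate (used to clip rescaled values)."""
    lo = np.full(len(COORD_NAMES), -np.inf)
    hi = np.full(len(COORD_NAMES), np.inf)
    for j, name in enumerate(COORD_NAMES):
        if name == "rho":
            lo[j], hi[j] = -1.0, 1.0
        elif name.endswith("_strength"):
            lo[j], hi[j] = 0.0, _STRENGTH_CAP
        elif name.endswith("_chi2"):
            lo[j] = 0.0
    return lo, hi


_COORD_LO, _COORD_HI = _coordinate_bounds()


def _solve_scale(
    sig_latent: np.ndarray,
    d_cont: np.ndarray,
    a: np.ndarray,
    scales: np.ndarray,
    L3: np.ndarray,
    target: float,
) -> float:
    """Scale factor c such that the realized separation hits ``target``.

    The realized continuous displacement is ``clip(x + c d_cont) - x``
    with per-coordinate domain clipping (strengths nonnegative, |rho|
    bounded by 1), so the separation is a piecewise-smooth increasing
    function of c; it is inverted by bisection.  ``a`` is the fixed
    sign-axis displacement in embedding coordinates.
    """

    def separation(c: float) -> float:
        realized = np.clip(sig_latent + c * d_cont, _COORD_LO, _COORD_HI) - sig_latent
        return float(np.linalg.norm(a + (realized / scales) @ L3))

    if separation(_MAX_SCALE) <= target:
        return _MAX_SCALE
    if separation(0.0) >= target:
        return 0.0
    lo_c, hi_c = 0.0, _MAX_SCALE
    for _ in range(50):
        mid = 0.5 * (lo_c + hi_c)
        if separation(mid) < target:
            lo_c = mid
        else:
            hi_c = mid
    return 0.5 * (lo_c + hi_c)


#: Direction-axis flip labels and their latent coordinate index.
_DIR_FLIP_COORD = {
    "tn": COORD_NAMES.index("tn_dir"),
    "surv_os": COORD_NAMES.index("os_dir"),
    "surv_dss": COORD_NAMES.index("dss_dir"),
    "surv_dfi": COORD_NAMES.index("dfi_dir"),
    "surv_pfi": COORD_NAMES.index("pfi_dir"),
    "immune": COORD_NAMES.index("immune_code"),
}


def _prune_direction_flips(
    records: list[CircuitryRecord],
    targets: list[float | None],
    int_templates: list[SideAnnotation],
    flip_sets: list[set[str]],
    params_list: list[dict],
    rebuild_seeds: list[int],
    sig_latents: list[np.ndarray],
    scales: np.ndarray,
    L3: np.ndarray,
) -> None:
    """Drop direction flips whose fixed displacement alone overshoots the target.

    Direction flips (tumor-normal, survival, immune polarity) are
    discrete and cannot be rescaled by the continuous calibration; if
    their combined embedding displacement already exceeds the target
    separation, flips are removed greedily (always keeping at least one)
    and the int side is re-derived with the reduced flip set.
    """
    for i, tgt in enumerate(targets):
        if tgt is None:
            continue
        dir_flips = [f for f in flip_sets[i] if f in _DIR_FLIP_COORD]
        if not dir_flips:
            continue
        # embedding displacement vector of each direction flip: -2 x_j e_j
        vecs = {}
        for f in dir_flips:
            j = _DIR_FLIP_COORD[f]
            delta = np.zeros(len(COORD_NAMES))
            delta[j] = -2.0 * sig_latents[i][j]
            vecs[f] = (delta / scales) @ L3
        kept = list(dir_flips)
        total = np.sum([vecs[f] for f in kept], axis=0)
        while len(kept) > 1 and np.linalg.norm(total) > tgt:
            # remove the flip whose removal brings the norm down the most
            best = min(kept, key=lambda f: np.linalg.norm(total - vecs[f]))
            kept.remove(best)
            total = total - vecs[best]
        if set(kept) != set(dir_flips):
            new_flips = (flip_sets[i] - set(dir_flips)) | set(kept)
            rng = np.random.default_rng(rebuild_seeds[i])
            ann, _ = _derive_int_side(
                records[i].sig, params_list[i], rng, flips=new_flips
            )
            int_templates[i] = ann
            flip_sets[i] = new_flips


def _calibrate_int_sides(
    records: list[CircuitryRecord],
    targets: list[float | None],
    int_templates: list[SideAnnotation],
    flip_sets: list[set[str]],
    params_list: list[dict],
    rebuild_seeds: list[int],
) -> list[CircuitryRecord]:
    """Iteratively rescale continuous divergence to hit target separations.

    Each pass fits the joint embedding of the current atlas, solves the
    per-circuitry scale factor against the clip-aware displacement map,
    and rebuilds the int annotations; the embedding is refit because
    rescaling feeds back into the column scales and principal axes.
    """
    sig_latents = [build_latent_vector(r.sig) for r in records]
    base_int_latents = [build_latent_vector(t) for t in int_templates]
    masks = [_scalable_mask(r.sig) for r in records]
    current = list(records)
    pruned = False
    for _ in range(_CALIBRATION_ITERATIONS):
        table = CircuitryTable(records=current, source_path="", dialect="generic")
        tensor, _ = build_latent_tensor(table)
        Z, means, scales = standardize(tensor)
        model = fit_pca(Z, means=means, scales=scales)
        L3 = model.loadings[:, :3]
        if not pruned:
            _prune_direction_flips(
                records, targets, int_templates, flip_sets, params_list,
                rebuild_seeds, sig_latents, scales, L3,
            )
            base_int_latents = [build_latent_vector(t) for t in int_templates]
            pruned = True
        new_records = []
        for i, rec in enumerate(current):
            if targets[i] is None:
                new_records.append(rec)
                continue
            delta = base_int_latents[i] - sig_latents[i]
            d_cont = np.where(masks[i], delta, 0.0)
            d_sign = delta - d_cont
            a = (d_sign / scales) @ L3
            c = _solve_scale(sig_latents[i], d_cont, a, scales, L3, targets[i])
            int_latent = d_sign + np.clip(
                sig_latents[i] + c * d_cont, _COORD_LO, _COORD_HI
            )
            new_ann = _annotation_from_latent(int_latent, int_templates[i])
            new_records.append(
                CircuitryRecord(
                    id=rec.id,
                    cancer_type=rec.cancer_type,
                    sig=rec.sig,
                    int_=new_ann,
                    omic_layer=rec.omic_layer,
                    metabolic_class=rec.metabolic_class,
                    pathway=rec.pathway,
                    phenotypic_layer=rec.phenotypic_layer,
                )
            )
        current = new_records
    return current


def simulate_atlas(spec: SimulationSpec) -> tuple[CircuitryTable, list[str]]:
    """Generate a synthetic atlas plus ground-truth component labels.

    Returns ``(table, truth)`` where ``truth[i]`` is the mixture
    component from which circuitry ``i`` was drawn.  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    components = rng.choice(
        len(MIXTURE_COMPONENTS), size=spec.n_circuitries, p=list(spec.mixture)
    )
    records: list[CircuitryRecord] = []
    truth: list[str] = []
    targets: list[float | None] = []
    int_templates: list[SideAnnotation] = []
    flip_sets: list[set[str]] = []
    params_list: list[dict] = []
    rebuild_seeds: list[int] = []
    for i in range(spec.n_circuitries):
        comp = MIXTURE_COMPONENTS[int(components[i])]
        params = spec.effect_scales[comp]
        sig = _enforce_availability(_draw_sig_side(spec, rng), params, rng)
        int_, flips = _derive_int_side(sig, params, rng)
        band = params.get("target_band")
        targets.append(float(rng.uniform(*band)) if band is not None else None)
        int_templates.append(int_)
        flip_sets.append(flips)
        params_list.append(params)
        rebuild_seeds.append(int(rng.integers(2**31)))
        records.append(
            CircuitryRecord(
                id=f"circ{i:05d}",
                cancer_type=f"CT{int(i % spec.n_strata):02d}",
                sig=sig,
                int_=int_,
                omic_layer="synthetic",
                metabolic_class="synthetic",
                pathway="synthetic",
                phenotypic_layer="synthetic",
            )
        )
        truth.append(comp)
    if any(t is not None for t in targets):
        records = _calibrate_int_sides(
            records, targets, int_templates, flip_sets, params_list, rebuild_seeds
        )
    return CircuitryTable(records=records, source_path="", dialect="generic"), truth


def simulate_null_atlas(spec: SimulationSpec) -> CircuitryTable:
    """Atlas under the null of random pairing: int drawn independently of sig."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_circuitries):
        records.append(
            CircuitryRecord(
                id=f"null{i:05d}",
                cancer_type=f"CT{int(i % spec.n_strata):02d}",
                sig=_draw_sig_side(spec, rng),
                int_=_draw_sig_side(spec, rng),
                omic_layer="synthetic",
                metabolic_class="synthetic",
                pathway="synthetic",
                phenotypic_layer="synthetic",
            )
        )
    return CircuitryTable(records=records, source_path="", dialect="generic")
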
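"""Synthetic scrub-mangrove populations with the sampling design the
analysis assumes: 15 trees in each of three height strata, a root system
per tree in which exactly two primary roots (and their secondaries) are
excavated, and per-root dry masses generated from the published per-class
equations plus configurable noise.

The generator emulates structure, not the field site: heights are uniform
within strata; stem diameter follows a power link D = α·h^β with
multiplicative lognormal noise; crown radii are proportional to height;
wood density is truncated-normal. Per-root masses come from the built-in
unexcavated-root equations on the root basal diameter, and the root-crown
mass from the per-class crown equation on the tree's predictors, each
times multiplicative lognormal (or optionally additive normal) noise, so
a fit to generated data should recover the generating coefficients —
exactly at zero noise. All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .mensuration import HeightClass, TreeRecord, diameter_convention
from .published_models import ModelRegistry, builtin_registry
from .allometry import predict
from .root_reconstruction import RootCrown, RootSample, RootType, TreeBGB, tree_bgb

__all__ = [
    "SimulationConfig",
    "simulate_trees",
    "simulate_root_system",
    "simulate_root_fit_data",
    "simulate_stand",
]

_CLASS_ORDER = (HeightClass.C1, HeightClass.C2, HeightClass.C3)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic population.

    Defaults mirror the sampling design (15 trees per class, two excavated
    primary roots per tree, strata 30–120 / >120–250 / >250–800 cm); the
    free distributional parameters are field-plausible for scrub Avicennia
    and documented in the methods note.
    """

    seed: int = 0
    n_per_class: int = 15
    height_bounds_cm: dict = field(
        default_factory=lambda: {"C1": (30.0, 120.0), "C2": (120.0, 250.0), "C3": (250.0, 800.0)}
    )
    # stem diameter link D = alpha * h^beta, multiplicative lognormal noise
    diameter_alpha: float = 0.07
    diameter_beta: float = 0.75
    diameter_cv: float = 0.10
    # crown radii proportional to height
    crown_r1_fraction: float = 0.35
    crown_r1_cv: float = 0.15
    crown_r2_min_ratio: float = 0.6
    # wood density, truncated normal (g cm^-3)
    density_mean: float = 0.70
    density_sd: float = 0.08
    density_bounds: tuple = (0.40, 1.00)
    # root system layout
    primaries_per_tree: int = 6
    secondaries_per_primary: int = 3
    excavated_primaries_per_tree: int = 2
    # per-class root basal-diameter ranges (cm), primary and secondary;
    # primaries taper, so the minimum excavatable diameter is roughly
    # class-independent while the maximum grows with tree size
    primary_bd_range: dict = field(
        default_factory=lambda: {"C1": (0.3, 2.0), "C2": (0.5, 3.5), "C3": (0.5, 6.0)}
    )
    secondary_bd_range: dict = field(
        default_factory=lambda: {"C1": (0.2, 1.0), "C2": (0.3, 1.5), "C3": (0.4, 1.8)}
    )
    # mass noise about the generating equations
    mass_cv: float = 0.10
    noise: str = "lognormal"  # or "additive"
    dry_fresh_ratio: float = 0.45
    subsample_fresh_g: float = 50.0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc = {
            k: tuple(v) if isinstance(v, list) and k in ("density_bounds",) else v
            for k, v in doc.items()
        }
        for key in ("height_bounds_cm", "primary_bd_range", "secondary_bd_range"):
            if key in doc:
                doc[key] = {c: tuple(b) for c, b in doc[key].items()}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        def listify(v):
            if isinstance(v, tuple):
                return [listify(x) for x in v]
            if isinstance(v, dict):
                return {k: listify(x) for k, x in v.items()}
            return v

        doc = {k: listify(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.primaries_per_tree < 1:
            raise ValueError("counts must be positive")
        if self.excavated_primaries_per_tree > self.primaries_per_tree:
            raise ValueError("cannot excavate more primaries than exist")
        if self.mass_cv < 0 or self.diameter_cv < 0 or self.crown_r1_cv < 0:
            raise ValueError("CVs must be non-negative")
        if self.noise not in ("lognormal", "additive"):
            raise ValueError("noise must be 'lognormal' or 'additive'")
        if not (0 < self.dry_fresh_ratio <= 1):
            raise ValueError("dry:fresh ratio must be in (0,1]")


def _mult_noise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _noisy_mass(
    rng: np.random.Generator, mean: float, cfg: SimulationConfig, ref: float | None = None
) -> float:
    """Noise a mass about its model mean.

    Lognormal noise is multiplicative with coefficient of variation
    ``mass_cv``. The additive option is homoscedastic — constant sd of
    ``mass_cv`` times a reference mass of the population (``ref``),
    matching the constant-variance additive-error convention of the
    fitted equations; the magnitude is taken so responses stay positive.
    """
    if cfg.mass_cv == 0:
        return mean
    if cfg.noise == "lognormal":
        return float(mean * _mult_noise(rng, cfg.mass_cv))
    sd = cfg.mass_cv * (ref if ref is not None else max(mean, 1e-12))
    return float(abs(mean + rng.normal(0.0, sd)))


def simulate_trees(config: SimulationConfig) -> list[TreeRecord]:
    """Generate n_per_class trees in each stratum, heights uniform within
    the class bounds, derived attributes via the mensuration rules."""
    rng = np.random.default_rng(config.seed)
    lo_d, hi_d = config.density_bounds
    a = (lo_d - config.density_mean) / config.density_sd
    b = (hi_d - config.density_mean) / config.density_sd
    trees: list[TreeRecord] = []
    for cls in _CLASS_ORDER:
        lo, hi = config.height_bounds_cm[cls.value]
        # strictly inside the stratum so class assignment is unambiguous
        heights = rng.uniform(lo + 1e-6, hi, size=config.n_per_class)
        for i, h in enumerate(heights):
            d = config.diameter_alpha * h**config.diameter_beta * _mult_noise(rng, config.diameter_cv)
            r1 = config.crown_r1_fraction * h * _mult_noise(rng, config.crown_r1_cv)
            r2 = r1 * rng.uniform(config.crown_r2_min_ratio, 1.0)
            rho = float(
                stats.truncnorm.rvs(
                    a, b, loc=config.density_mean, scale=config.density_sd, random_state=rng
                )
            )
            volume = 100.0  # disk volume, cm^3; mass backs out of rho
            trees.append(
                TreeRecord(
                    tree_id=f"{cls.value}-{i + 1:03d}",
                    height_cm=float(h),
                    diameter_cm=float(d),
                    diameter_kind=diameter_convention(h),
                    crown_r1_cm=float(r1),
                    crown_r2_cm=float(r2),
                    disk_dry_mass_g=rho * volume,
                    disk_volume_cm3=volume,
                )
            )
    return trees


def simulate_root_system(
    tree: TreeRecord,
    config: SimulationConfig,
    registry: ModelRegistry | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[RootSample], RootCrown]:
    """Generate one tree's root system.

    Per-root dry masses come from the per-class published equations on the
    root basal diameter, times noise; exactly
    ``excavated_primaries_per_tree`` primaries are flagged excavated, with
    fresh and subsample masses consistent with the configured D:F ratio.
    Secondary roots attach to the excavated primaries (and are excavated
    with them) or to unexcavated ones. The root-crown mass comes from the
    per-class crown equation on the tree's predictors.
    """
    reg = registry or builtin_registry()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cls = tree.height_class.value
    primary_model = reg.get_model(cls, "UNEXCAVATED_PRIMARY")
    secondary_model = reg.get_model(cls, "UNEXCAVATED_SECONDARY")
    crown_model = reg.get_model(cls, "ROOT_CROWN")

    samples: list[RootSample] = []
    excavated_idx = set(range(config.excavated_primaries_per_tree))
    p_lo, p_hi = config.primary_bd_range[cls]
    s_lo, s_hi = config.secondary_bd_range[cls]
    # homoscedastic-noise reference: predicted mass at the mid-range diameter
    p_ref = float(predict(primary_model, {"x": (p_lo + p_hi) / 2.0}))
    s_ref = max(float(predict(secondary_model, {"x": (s_lo + s_hi) / 2.0})), 1e-12)
    for p in range(config.primaries_per_tree):
        excavated = p in excavated_idx
        bd = float(rng.uniform(p_lo, p_hi))
        dry = _noisy_mass(rng, predict(primary_model, {"x": bd}), config, ref=p_ref)
        samples.append(_make_sample(tree.tree_id, RootType.PRIMARY, bd, excavated, dry, config))
        for _ in range(config.secondaries_per_primary):
            sbd = float(rng.uniform(s_lo, s_hi))
            sdry = _noisy_mass(
                rng, max(predict(secondary_model, {"x": sbd}), 0.0), config, ref=s_ref
            )
            samples.append(_make_sample(tree.tree_id, RootType.SECONDARY, sbd, excavated, sdry, config))

    crown_mean = max(float(predict(crown_model, tree.predictors())), 0.0)
    crown = RootCrown(tree_id=tree.tree_id, dry_mass_kg=_noisy_mass(rng, crown_mean, config))
    return samples, crown


def _make_sample(
    tree_id: str, rtype: RootType, bd: float, excavated: bool, dry_kg: float, cfg: SimulationConfig
) -> RootSample:
    if not excavated:
        # unexcavated roots exist physically; their dry mass is the latent
        # truth the reconstruction estimates. Keep it out of the record.
        return RootSample(
            tree_id=tree_id, root_type=rtype, basal_diameter_cm=bd, excavated=False
        )
    df = cfg.dry_fresh_ratio
    return RootSample(
        tree_id=tree_id,
        root_type=rtype,
        basal_diameter_cm=bd,
        excavated=True,
        fresh_mass_kg=dry_kg / df,
        subsample_fresh_g=cfg.subsample_fresh_g,
        subsample_dry_g=cfg.subsample_fresh_g * df,
    )


def simulate_root_fit_data(
    registry: ModelRegistry | None,
    height_class: str,
    compartment: str,
    n: int = 200,
    cv: float = 0.05,
    seed: int = 0,
    noise: str = "additive",
):
    """(basal diameter, dry mass) pairs for refitting one per-class root
    equation, generated by simulating root systems with every root
    excavated.

    The default constant-variance ("additive") noise matches the
    additive-error convention the equations assume, which is the setting
    used for parameter-recovery checks. Returns a DataFrame with columns
    x (cm) and y (kg), at most ``n`` rows.
    """
    import pandas as pd

    reg = registry or builtin_registry()
    cfg = SimulationConfig(
        seed=seed,
        n_per_class=(n + 5) // 6,
        mass_cv=cv,
        noise=noise,
        primaries_per_tree=6,
        excavated_primaries_per_tree=6,
    )
    trees = [t for t in simulate_trees(cfg) if t.height_class.value == height_class]
    rng = np.random.default_rng(seed + 1)
    rtype = RootType.PRIMARY if compartment == "UNEXCAVATED_PRIMARY" else RootType.SECONDARY
    rows = []
    for tree in trees:
        samples, _ = simulate_root_system(tree, cfg, reg, rng)
        rows.extend(
            {"x": s.basal_diameter_cm, "y": s.dry_mass_kg}
            for s in samples
            if s.root_type is rtype and s.dry_mass_kg is not None and s.dry_mass_kg > 0
        )
    return pd.DataFrame(rows[:n])


def simulate_stand(
    config: SimulationConfig,
    stems_per_ha: dict[str, float],
    registry: ModelRegistry | None = None,
) -> dict:
    """Generate a stand and expand per-tree masses to per-class densities.

    ``stems_per_ha`` maps height class to stem density. Per-class BGB
    density (Mg ha⁻¹) = mean reconstructed tree BGB (kg) × stems ha⁻¹ /
    1000. Returns trees, root data, per-tree BGB ledgers and densities.
    """
    reg = registry or builtin_registry()
    rng = np.random.default_rng(config.seed)
    trees = simulate_trees(replace(config, seed=int(rng.integers(2**31 - 1))))
    all_samples: list[RootSample] = []
    crowns: dict[str, RootCrown] = {}
    ledgers: list[TreeBGB] = []
    for tree in trees:
        samples, crown = simulate_root_system(tree, config, reg, rng)
        all_samples.extend(samples)
        crowns[tree.tree_id] = crown
    # reconstruct with the same (generating) models
    from .root_reconstruction import estimate_unexcavated, total_root_mass

    models = {
        (cls, RootType.PRIMARY): reg.get_model(cls.value, "UNEXCAVATED_PRIMARY")
        for cls in _CLASS_ORDER
    } | {
        (cls, RootType.SECONDARY): reg.get_model(cls.value, "UNEXCAVATED_SECONDARY")
        for cls in _CLASS_ORDER
    }
    classes = {t.tree_id: t.height_class for t in trees}
    filled = estimate_unexcavated(all_samples, models, classes)
    by_tree: dict[str, list[RootSample]] = {}
    for s in filled:
        by_tree.setdefault(s.tree_id, []).append(s)
    for tree in trees:
        mine = by_tree[tree.tree_id]
        ledgers.append(
            tree_bgb(
                crowns[tree.tree_id],
                primary_kg=total_root_mass(mine, RootType.PRIMARY),
                secondary_kg=total_root_mass(mine, RootType.SECONDARY),
            )
        )
    bgb_density = {}
    for cls in _CLASS_ORDER:
        masses = [
            l.total_kg for l, t in zip(ledgers, trees) if t.height_class == cls
        ]
        bgb_density[cls.value] = float(np.mean(masses)) * stems_per_ha[cls.value] / 1000.0
    return {
        "trees": trees,
        "root_samples": filled,
        "root_crowns": crowns,
        "tree_bgb": ledgers,
        "bgb_mg_ha": bgb_density,
    }
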
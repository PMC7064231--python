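"""Per-tree below-ground biomass from partially excavated root systems.

Each tree's root system is compartmentalised into the root crown, primary
roots (originating at the crown) and secondary roots (originating on
primaries). Two primary roots per tree (plus their secondaries) were dug
out and weighed; every other root contributes a model-predicted dry mass
from its basal diameter. Total BGB = root crown + primary + secondary.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .allometry import AllometricModel, ModelFormName, predict
from .mensuration import DomainError, HeightClass

__all__ = [
    "RootType",
    "RootSample",
    "RootCrown",
    "TreeBGB",
    "dry_from_fresh",
    "estimate_unexcavated",
    "total_root_mass",
    "tree_bgb",
    "reconstruct_tree",
    "read_root_samples",
    "read_root_crowns",
    "write_root_samples",
    "write_root_crowns",
]


class RootType(str, enum.Enum):
    PRIMARY = "PRIMARY"
    SECONDARY = "SECONDARY"


@dataclass
class RootSample:
    """One root. Excavated roots carry a measured fresh mass plus the
    fresh/dry subsample pair that fixes their D:F ratio; unexcavated roots
    get ``dry_mass_kg`` filled by :func:`estimate_unexcavated`."""

    tree_id: str
    root_type: RootType
    basal_diameter_cm: float
    excavated: bool
    length_cm: float | None = None
    fresh_mass_kg: float | None = None
    subsample_fresh_g: float | None = None
    subsample_dry_g: float | None = None
    dry_mass_kg: float | None = None

    def __post_init__(self) -> None:
        if self.basal_diameter_cm <= 0:
            raise DomainError(f"root of tree {self.tree_id}: non-positive basal diameter")
        if self.excavated:
            needed = (self.fresh_mass_kg, self.subsample_fresh_g, self.subsample_dry_g)
            if any(v is None for v in needed) and self.dry_mass_kg is None:
                raise DomainError(
                    f"excavated root of tree {self.tree_id} needs fresh mass and "
                    "subsample masses (or a direct dry mass)"
                )
            if self.dry_mass_kg is None:
                self.dry_mass_kg = dry_from_fresh(
                    self.fresh_mass_kg, self.subsample_fresh_g, self.subsample_dry_g
                )
        if self.dry_mass_kg is not None and self.dry_mass_kg < 0:
            raise DomainError(f"root of tree {self.tree_id}: negative dry mass")


@dataclass(frozen=True)
class RootCrown:
    """Dry mass (kg) of the excavated root crown of one tree."""

    tree_id: str
    dry_mass_kg: float

    def __post_init__(self) -> None:
        if self.dry_mass_kg < 0:
            raise DomainError(f"root crown of tree {self.tree_id}: negative mass")


@dataclass(frozen=True)
class TreeBGB:
    """Below-ground biomass of one tree, by compartment (kg)."""

    tree_id: str
    crown_kg: float
    primary_kg: float
    secondary_kg: float

    def __post_init__(self) -> None:
        for name in ("crown_kg", "primary_kg", "secondary_kg"):
            if getattr(self, name) < 0:
                raise DomainError(f"tree {self.tree_id}: negative {name}")

    @property
    def total_kg(self) -> float:
        return self.crown_kg + self.primary_kg + self.secondary_kg


def dry_from_fresh(fresh_mass_kg: float, subsample_fresh_g: float, subsample_dry_g: float) -> float:
    """Whole-root dry mass (kg) from its fresh mass and the oven-dry
    subsample ratio: fresh x (subsample dry / subsample fresh)."""
    if subsample_fresh_g <= 0:
        raise DomainError("subsample fresh mass must be positive")
    if subsample_dry_g < 0 or subsample_dry_g > subsample_fresh_g:
        raise DomainError("subsample dry mass must lie in [0, fresh]")
    if fresh_mass_kg < 0:
        raise DomainError("fresh mass must be non-negative")
    return fresh_mass_kg * (subsample_dry_g / subsample_fresh_g)


def estimate_unexcavated(
    samples: list[RootSample],
    models: dict[tuple[HeightClass, RootType], AllometricModel],
    tree_classes: dict[str, HeightClass],
    calibration_ranges: dict[tuple[HeightClass, RootType], tuple[float, float]] | None = None,
) -> list[RootSample]:
    """Fill the dry mass of every unexcavated root from its basal diameter.

    ``models`` maps (height class, root type) to the per-class equation;
    prediction uses the root basal diameter as the single predictor ``x``.
    Negative predictions (possible for the C1 secondary quadratic at very
    small diameters) are clamped to zero with a warning, since dry mass is
    non-negative. Diameters outside a model's calibration range predict
    normally but emit an extrapolation warning.
    """
    out: list[RootSample] = []
    for s in samples:
        if s.excavated:
            out.append(s)
            continue
        cls = tree_classes.get(s.tree_id)
        if cls is None:
            raise DomainError(f"no height class known for tree {s.tree_id}")
        key = (HeightClass(cls), RootType(s.root_type))
        if key not in models:
            raise DomainError(
                f"no unexcavated-root model for (class={key[0].value}, type={key[1].value})"
            )
        if calibration_ranges and key in calibration_ranges:
            lo, hi = calibration_ranges[key]
            if not (lo <= s.basal_diameter_cm <= hi):
                warnings.warn(
                    f"tree {s.tree_id}: basal diameter {s.basal_diameter_cm} cm outside "
                    f"calibration range [{lo}, {hi}] of the {key[0].value}/{key[1].value} model",
                    stacklevel=2,
                )
        mass = predict(models[key], {"x": s.basal_diameter_cm})
        if mass < 0:
            warnings.warn(
                f"tree {s.tree_id}: negative predicted root mass {mass:.4g} kg clamped to 0",
                stacklevel=2,
            )
            mass = 0.0
        out.append(replace(s, dry_mass_kg=float(mass)))
    return out


def total_root_mass(samples: list[RootSample], root_type: RootType) -> float:
    """Summed dry mass (kg) of one root type: excavated + estimated."""
    total = 0.0
    for s in samples:
        if RootType(s.root_type) != RootType(root_type):
            continue
        if s.dry_mass_kg is None:
            state = "excavated" if s.excavated else "unexcavated"
            raise DomainError(
                f"{state} {s.root_type} root of tree {s.tree_id} has no dry mass; "
                "run estimate_unexcavated first"
            )
        total += s.dry_mass_kg
    return total


def tree_bgb(crown: RootCrown, primary_kg: float, secondary_kg: float) -> TreeBGB:
    """Assemble the per-tree BGB ledger; total = crown + primary + secondary."""
    if primary_kg < 0 or secondary_kg < 0:
        raise DomainError(f"tree {crown.tree_id}: negative root compartment mass")
    return TreeBGB(
        tree_id=crown.tree_id,
        crown_kg=crown.dry_mass_kg,
        primary_kg=primary_kg,
        secondary_kg=secondary_kg,
    )


def reconstruct_tree(
    tree_id: str,
    samples: list[RootSample],
    crown: RootCrown,
    models: dict[tuple[HeightClass, RootType], AllometricModel],
    height_class: HeightClass,
    calibration_ranges=None,
) -> TreeBGB:
    """Full reconstruction for one tree: estimate unexcavated roots, sum
    compartments, and assemble the BGB ledger."""
    mine = [s for s in samples if s.tree_id == tree_id]
    filled = estimate_unexcavated(
        mine, models, {tree_id: height_class}, calibration_ranges=calibration_ranges
    )
    return tree_bgb(
        crown,
        primary_kg=total_root_mass(filled, RootType.PRIMARY),
        secondary_kg=total_root_mass(filled, RootType.SECONDARY),
    )


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s not in _BOOL_MAP:
        raise DomainError(f"cannot parse excavated flag {v!r}")
    return _BOOL_MAP[s]


def read_root_samples(path) -> list[RootSample]:
    """Root-sample CSV: tree_id, root_type, basal_diameter_cm, length_cm,
    excavated, fresh_mass_kg, subsample_fresh_g, subsample_dry_g."""
    df = pd.read_csv(path, dtype={"tree_id": str, "root_type": str})
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            RootSample(
                tree_id=row.tree_id,
                root_type=RootType(row.root_type),
                basal_diameter_cm=float(row.basal_diameter_cm),
                excavated=_parse_bool(row.excavated),
                length_cm=_nan_none(getattr(row, "length_cm", None)),
                fresh_mass_kg=_nan_none(getattr(row, "fresh_mass_kg", None)),
                subsample_fresh_g=_nan_none(getattr(row, "subsample_fresh_g", None)),
                subsample_dry_g=_nan_none(getattr(row, "subsample_dry_g", None)),
                dry_mass_kg=_nan_none(getattr(row, "dry_mass_kg", None)),
            )
        )
    return samples


def _nan_none(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_root_crowns(path) -> list[RootCrown]:
    df = pd.read_csv(path, dtype={"tree_id": str})
    return [RootCrown(tree_id=r.tree_id, dry_mass_kg=float(r.dry_mass_kg)) for r in df.itertuples(index=False)]


def write_root_samples(samples: list[RootSample], path) -> None:
    pd.DataFrame(
        [
            {
                "tree_id": s.tree_id,
                "root_type": s.root_type.value,
                "basal_diameter_cm": s.basal_diameter_cm,
                "length_cm": s.length_cm,
                "excavated": s.excavated,
                "fresh_mass_kg": s.fresh_mass_kg,
                "subsample_fresh_g": s.subsample_fresh_g,
                "subsample_dry_g": s.subsample_dry_g,
                "dry_mass_kg": s.dry_mass_kg,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def write_root_crowns(crowns: list[RootCrown], path) -> None:
    pd.DataFrame([{"tree_id": c.tree_id, "dry_mass_kg": c.dry_mass_kg} for c in crowns]).to_csv(
        path, index=False
    )
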
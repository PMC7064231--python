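"""Tree-level structural measurements for scrub mangrove inventory.

All internal lengths are centimetres (heights included — field sheets list
height in metres but every model here consumes cm), masses in grams or
kilograms as annotated, densities in g cm^-3.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HeightClass",
    "DiameterKind",
    "TreeRecord",
    "CrownGeometry",
    "assign_height_class",
    "diameter_convention",
    "crown_area",
    "crown_volume",
    "wood_density",
    "dry_fresh_ratio",
    "read_tree_inventory",
    "write_tree_inventory",
]

#: height strata (cm): shrubs, short trees, tall/emergent trees
HEIGHT_CLASS_BOUNDS_CM = {"C1": (30.0, 120.0), "C2": (120.0, 250.0), "C3": (250.0, math.inf)}

#: stems at least this tall (cm) are measured at breast height (130 cm)
DBH_MIN_HEIGHT_CM = 350.0

#: plausible wood basic density for mangrove stems, g cm^-3
DENSITY_PLAUSIBLE_RANGE = (0.2, 1.2)


class HeightClass(str, enum.Enum):
    """Height stratum of a scrub-forest tree: C1 shrubs (30-120 cm),
    C2 short trees (>120-250 cm), C3 tall trees (>250 cm)."""

    C1 = "C1"
    C2 = "C2"
    C3 = "C3"


class DiameterKind(str, enum.Enum):
    """Where the stem diameter was taken: breast height (130 cm) for trees
    of at least 3.5 m, else 30 cm above ground (basal diameter)."""

    DBH_130 = "DBH_130"
    BASAL_30 = "BASAL_30"


class DomainError(ValueError):
    """A measurement outside the physical or sampling domain."""


def assign_height_class(height_cm: float) -> HeightClass:
    """Assign a tree to its height stratum.

    C1 covers [30, 120] cm, C2 (120, 250] cm, C3 everything taller.
    Heights below 30 cm fall outside the smallest observed stratum and
    raise :class:`DomainError`.
    """
    if not math.isfinite(height_cm) or height_cm < 30.0:
        raise DomainError(
            f"height {height_cm!r} cm is below the smallest stratum "
            "(strata: C1 [30,120], C2 (120,250], C3 >250 cm)"
        )
    if height_cm <= 120.0:
        return HeightClass.C1
    if height_cm <= 250.0:
        return HeightClass.C2
    return HeightClass.C3


def diameter_convention(height_cm: float) -> DiameterKind:
    """Measurement convention for the stem diameter of a tree of this height.

    Trees of at least 3.5 m take DBH at 130 cm; shorter trees take the
    basal diameter at 30 cm above ground.
    """
    if not math.isfinite(height_cm) or height_cm <= 0:
        raise DomainError(f"height must be positive, got {height_cm!r}")
    return DiameterKind.DBH_130 if height_cm >= DBH_MIN_HEIGHT_CM else DiameterKind.BASAL_30


def crown_area(r1_cm: float, r2_cm: float) -> float:
    """Crown area (cm^2) from the greatest (R1) and smallest (R2) crown radii.

    Evaluates (R1/2)·(R2/2)·π exactly as the field protocol defines it —
    the two stored radii are halved inside the formula. R1 must be entered
    first (R1 >= R2 >= 0).
    """
    if r2_cm < 0 or r1_cm < 0:
        raise DomainError("crown radii must be non-negative")
    if r1_cm < r2_cm:
        raise DomainError(f"radii must be ordered R1 >= R2, got R1={r1_cm}, R2={r2_cm}")
    return (r1_cm / 2.0) * (r2_cm / 2.0) * math.pi


def crown_volume(area_cm2: float, height_cm: float) -> float:
    """Crown volume (cm^3) as crown area x total height."""
    if area_cm2 < 0 or height_cm < 0:
        raise DomainError("crown area and height must be non-negative")
    return area_cm2 * height_cm


def wood_density(dry_mass_g: float, volume_cm3: float) -> float:
    """Wood basic density rho = M/V (g cm^-3) from an oven-dry disk mass and
    its green volume (water displacement).

    Emits a warning when the result leaves the plausible 0.2-1.2 g cm^-3
    range; field samples can be odd, so only impossibilities are errors.
    """
    if volume_cm3 <= 0:
        raise DomainError(f"disk volume must be positive, got {volume_cm3!r}")
    if dry_mass_g < 0:
        raise DomainError(f"dry mass must be non-negative, got {dry_mass_g!r}")
    rho = dry_mass_g / volume_cm3
    lo, hi = DENSITY_PLAUSIBLE_RANGE
    if not (lo <= rho <= hi):
        warnings.warn(
            f"wood density {rho:.3f} g cm^-3 outside plausible range [{lo}, {hi}]",
            stacklevel=2,
        )
    return rho


def dry_fresh_ratio(dry_mass: float, fresh_mass: float) -> float:
    """Dry-to-fresh mass ratio D:F of a subsample, in (0, 1].

    Used to convert whole-compartment fresh mass to dry mass
    (dry = fresh x D:F).
    """
    if fresh_mass <= 0:
        raise DomainError(f"fresh mass must be positive, got {fresh_mass!r}")
    if dry_mass < 0 or dry_mass > fresh_mass:
        raise DomainError(
            f"dry mass must satisfy 0 <= dry <= fresh, got dry={dry_mass}, fresh={fresh_mass}"
        )
    return dry_mass / fresh_mass


@dataclass(frozen=True)
class CrownGeometry:
    """Derived crown ellipse: area (cm^2) and volume (cm^3)."""

    area_cm2: float
    volume_cm3: float


@dataclass
class TreeRecord:
    """One measured tree of the destructive inventory.

    ``diameter_kind`` records whether ``diameter_cm`` is DBH (taken at
    130 cm, trees >= 3.5 m) or basal diameter (taken at 30 cm). Disk
    measurements are the stem disk used for wood density and may be absent.
    """

    tree_id: str
    height_cm: float
    diameter_cm: float
    diameter_kind: DiameterKind
    crown_r1_cm: float
    crown_r2_cm: float
    disk_dry_mass_g: float | None = None
    disk_volume_cm3: float | None = None
    height_class: HeightClass | None = None

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise DomainError(f"tree {self.tree_id}: non-positive height")
        if self.diameter_cm <= 0:
            raise DomainError(f"tree {self.tree_id}: non-positive diameter")
        if self.crown_r2_cm < 0 or self.crown_r1_cm < self.crown_r2_cm:
            raise DomainError(f"tree {self.tree_id}: crown radii must satisfy R1 >= R2 >= 0")
        for name in ("disk_dry_mass_g", "disk_volume_cm3"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"tree {self.tree_id}: {name} must be positive when present")
        expected_kind = diameter_convention(self.height_cm)
        if self.diameter_kind != expected_kind:
            raise DomainError(
                f"tree {self.tree_id}: diameter_kind {self.diameter_kind.value} inconsistent "
                f"with height {self.height_cm} cm (expected {expected_kind.value})"
            )
        cls = assign_height_class(self.height_cm)
        if self.height_class is None:
            self.height_class = cls
        elif HeightClass(self.height_class) != cls:
            raise DomainError(
                f"tree {self.tree_id}: height_class {self.height_class} inconsistent "
                f"with height {self.height_cm} cm (expected {cls.value})"
            )
        else:
            self.height_class = HeightClass(self.height_class)

    @property
    def crown(self) -> CrownGeometry:
        area = crown_area(self.crown_r1_cm, self.crown_r2_cm)
        return CrownGeometry(area, crown_volume(area, self.height_cm))

    @property
    def wood_density_g_cm3(self) -> float | None:
        if self.disk_dry_mass_g is None or self.disk_volume_cm3 is None:
            return None
        return wood_density(self.disk_dry_mass_g, self.disk_volume_cm3)

    def predictors(self) -> dict[str, float]:
        """Predictor map for allometric prediction: D, h, V, rho."""
        out = {"D": self.diameter_cm, "h": self.height_cm, "V": self.crown.volume_cm3}
        rho = self.wood_density_g_cm3
        if rho is not None:
            out["rho"] = rho
        return out


_INVENTORY_COLUMNS = [
    "tree_id",
    "height_cm",
    "diameter_cm",
    "diameter_kind",
    "crown_r1_cm",
    "crown_r2_cm",
    "disk_dry_mass_g",
    "disk_volume_cm3",
]


def _normalize_decimal(series: pd.Series) -> pd.Series:
    # published tables print comma decimal separators; accept both
    if series.dtype == object:
        series = series.astype(str).str.strip().str.replace(",", ".", regex=False)
        series = series.replace({"": None, "-": None, "nan": None, "None": None})
    return pd.to_numeric(series)


def read_tree_inventory(path) -> list[TreeRecord]:
    """Read a tree-inventory CSV (one row per tree) into TreeRecords.

    Numeric columns accept both "." and "," decimal separators.
    """
    df = pd.read_csv(path, dtype={"tree_id": str, "diameter_kind": str})
    missing = [c for c in _INVENTORY_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise DomainError(f"tree inventory missing required columns: {missing}")
    for col in df.columns:
        if col not in ("tree_id", "diameter_kind", "height_class"):
            df[col] = _normalize_decimal(df[col])
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TreeRecord(
                tree_id=row.tree_id,
                height_cm=row.height_cm,
                diameter_cm=row.diameter_cm,
                diameter_kind=DiameterKind(row.diameter_kind),
                crown_r1_cm=row.crown_r1_cm,
                crown_r2_cm=row.crown_r2_cm,
                disk_dry_mass_g=_opt(getattr(row, "disk_dry_mass_g", None)),
                disk_volume_cm3=_opt(getattr(row, "disk_volume_cm3", None)),
            )
        )
    return records


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def write_tree_inventory(trees: list[TreeRecord], path) -> None:
    rows = [
        {
            "tree_id": t.tree_id,
            "height_cm": t.height_cm,
            "diameter_cm": t.diameter_cm,
            "diameter_kind": t.diameter_kind.value,
            "crown_r1_cm": t.crown_r1_cm,
            "crown_r2_cm": t.crown_r2_cm,
            "disk_dry_mass_g": t.disk_dry_mass_g,
            "disk_volume_cm3": t.disk_volume_cm3,
            "height_class": t.height_class.value,
        }
        for t in trees
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
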
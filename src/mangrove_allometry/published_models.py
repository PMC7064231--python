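"""Registry of the published scrub-mangrove allometric equations.

Built-in entries cover, digit-exact:

* six per-class unexcavated-root equations (dry mass, kg, from root basal
  diameter x, cm) — power forms except the C1 secondary-root quadratic;
* nine per-class below-ground equations (ROOT = primary+secondary,
  ROOT_CROWN, TOTAL_BGB) on stem diameter D (cm), height h (cm), crown
  volume V (cm³) and wood density rho (g cm⁻³);
* the generalist all-classes total-BGB power model y = 0.07577·D^1.98745.

Above-ground (AGB) equations are not reprinted in the main text; the AGB
slot ships empty and is filled from a user JSON document (schema below),
whose entries may carry a log-back-transform correction factor ``cf``.

Coefficients are stored as their printed decimal strings and parsed on
use, so a save/load round-trip preserves every digit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .allometry import AllometricModel, ModelForm, ModelFormName

__all__ = [
    "Compartment",
    "GENERALIST",
    "RegistryEntry",
    "ModelRegistry",
    "builtin_registry",
    "load_registry",
    "validate_registry",
]

GENERALIST = "GENERALIST"

#: registry compartments
COMPARTMENTS = (
    "UNEXCAVATED_PRIMARY",
    "UNEXCAVATED_SECONDARY",
    "ROOT",
    "ROOT_CROWN",
    "TOTAL_BGB",
    "AGB",
)

Compartment = str  # one of COMPARTMENTS

_FORMS = {f.value: f for f in ModelFormName}

# (scope, compartment, form, predictors, coefficient strings, fit digits, provenance)
# fit digits: (n, rmse, r2_adj, mpe) as printed; aic included where printed.
_BUILTIN_ROWS: tuple[dict, ...] = (
    # -- unexcavated-root equations (predictor x = root basal diameter, cm) --
    dict(scope="C1", compartment="UNEXCAVATED_SECONDARY", form="QUADRATIC", predictors=("x",),
         coefficients=("0.0236337", "-0.0052021", "0.0001993"),
         fit=dict(n=17, rmse=0.002, r2_adj=0.94, mpe=-0.8),
         provenance="published unexcavated-root equation, class C1 secondary"),
    dict(scope="C1", compartment="UNEXCAVATED_PRIMARY", form="POWER", predictors=("x",),
         coefficients=("0.0272117", "2.5584838"),
         fit=dict(n=13, rmse=0.006, r2_adj=0.86, mpe=-0.12),
         provenance="published unexcavated-root equation, class C1 primary"),
    dict(scope="C2", compartment="UNEXCAVATED_SECONDARY", form="POWER", predictors=("x",),
         coefficients=("0.0456687", "3.4475717"),
         fit=dict(n=32, rmse=0.004, r2_adj=0.97, mpe=-0.75),
         provenance="published unexcavated-root equation, class C2 secondary"),
    dict(scope="C2", compartment="UNEXCAVATED_PRIMARY", form="POWER", predictors=("x",),
         coefficients=("0.0873721", "1.6762250"),
         fit=dict(n=22, rmse=0.084, r2_adj=0.86, mpe=-0.17),
         provenance="published unexcavated-root equation, class C2 primary"),
    dict(scope="C3", compartment="UNEXCAVATED_SECONDARY", form="POWER", predictors=("x",),
         coefficients=("0.0413852", "3.7995342"),
         fit=dict(n=9, rmse=0.005, r2_adj=0.98, mpe=0.20),
         provenance="published unexcavated-root equation, class C3 secondary"),
    dict(scope="C3", compartment="UNEXCAVATED_PRIMARY", form="POWER", predictors=("x",),
         coefficients=("0.0075510", "3.1628440"),
         fit=dict(n=22, rmse=0.348, r2_adj=0.98, mpe=0.23),
         provenance="published unexcavated-root equation, class C3 primary"),
    # -- below-ground biomass equations --
    dict(scope="C1", compartment="ROOT", form="LINEAR_MULTI", predictors=("h", "rho"),
         coefficients=("0.114", "0.005", "-0.682"),
         fit=dict(n=8, rmse=0.03, aic=-31.84, r2_adj=0.93, mpe=0.008),
         provenance="published BGB equation, class C1 root (primary+secondary)"),
    dict(scope="C1", compartment="ROOT_CROWN", form="LINEAR_MULTI", predictors=("h", "D", "V"),
         coefficients=("-0.021", "0.000", "0.021", "6.53E-08"),
         fit=dict(n=9, rmse=0.002, aic=-80.74, r2_adj=0.98, mpe=-0.077),
         provenance="published BGB equation, class C1 root crown"),
    # printed "y = a*b*h+cD+drho"; read as the linear a + b·h + c·D + d·rho,
    # consistent with the class's other (linear) equations
    dict(scope="C1", compartment="TOTAL_BGB", form="LINEAR_MULTI", predictors=("h", "D", "rho"),
         coefficients=("0.038", "0.002", "0.082", "-0.3781"),
         fit=dict(n=8, rmse=0.02, aic=-31.65, r2_adj=0.92, mpe=0.001),
         provenance="published BGB equation, class C1 total (linear reading)"),
    dict(scope="C2", compartment="ROOT", form="POWER", predictors=("D",),
         coefficients=("0.465", "1.024"),
         fit=dict(n=11, rmse=0.37, aic=15.45, r2_adj=0.94, mpe=-0.033),
         provenance="published BGB equation, class C2 root"),
    dict(scope="C2", compartment="ROOT_CROWN", form="LINEAR_MULTI", predictors=("h", "D", "V", "rho"),
         coefficients=("0.814", "-0.003", "0.017", "7.27E-08", "-0.660"),
         fit=dict(n=8, rmse=0.03, aic=-27.50, r2_adj=0.95, mpe=-0.083),
         provenance="published BGB equation, class C2 root crown"),
    dict(scope="C2", compartment="TOTAL_BGB", form="POWER", predictors=("D",),
         coefficients=("0.468", "1.036"),
         fit=dict(n=11, rmse=0.41, aic=17.76, r2_adj=0.93, mpe=-0.038),
         provenance="published BGB equation, class C2 total"),
    dict(scope="C3", compartment="ROOT", form="POWER_MULTI", predictors=("D", "h", "V", "rho"),
         coefficients=("0.003", "-2.180", "2.572", "-0.024", "5.275"),
         fit=dict(n=8, rmse=0.55, aic=25.17, r2_adj=0.98, mpe=-0.058),
         provenance="published BGB equation, class C3 root"),
    dict(scope="C3", compartment="ROOT_CROWN", form="POWER_MULTI", predictors=("D", "h", "V"),
         coefficients=("8.63E-10", "1.138", "2.730", "0.117"),
         fit=dict(n=9, rmse=0.24, aic=10.12, r2_adj=0.92, mpe=-0.231),
         provenance="published BGB equation, class C3 root crown"),
    dict(scope="C3", compartment="TOTAL_BGB", form="POWER_MULTI", predictors=("D", "h", "V", "rho"),
         coefficients=("0.002", "-1.381", "2.205", "0.005", "4.263"),
         fit=dict(n=8, rmse=0.16, aic=4.93, r2_adj=0.99, mpe=0.003),
         provenance="published BGB equation, class C3 total"),
    # -- generalist all-classes model --
    dict(scope=GENERALIST, compartment="TOTAL_BGB", form="POWER", predictors=("D",),
         coefficients=("0.07577", "1.98745"),
         fit=dict(rmse=0.85, aic=58.69, r2_adj=0.96, mpe=-0.77),
         provenance="published generalist total-BGB equation"),
)


@dataclass(frozen=True)
class RegistryEntry:
    """One registry row; ``coefficients`` keep their decimal strings."""

    scope: str
    compartment: Compartment
    form: ModelForm
    coefficients: tuple[str, ...]
    provenance: str
    cf: float | None = None
    fit_digits: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    builtin: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.scope, self.compartment)

    def model(self) -> AllometricModel:
        return AllometricModel(
            form=self.form,
            coefficients=tuple(float(c) for c in self.coefficients),
            scope=(self.scope, self.compartment),
            cf=self.cf,
        )

    def to_json(self) -> dict:
        out = {
            "scope": self.scope,
            "compartment": self.compartment,
            "form": self.form.name.value,
            "predictors": list(self.form.predictor_names),
            "coefficients": list(self.coefficients),
            "provenance": self.provenance,
            "units": self.units,
        }
        if self.cf is not None:
            out["cf"] = self.cf
        return out


_DEFAULT_UNITS = {"x": "cm", "D": "cm", "h": "cm", "V": "cm3", "rho": "g/cm3", "response": "kg"}


def _entry_from_row(row: dict, builtin: bool) -> RegistryEntry:
    try:
        form = ModelForm(_FORMS[row["form"]], tuple(row["predictors"]))
    except KeyError as exc:
        raise SchemaError(f"/form: unknown model form {row.get('form')!r}") from exc
    coefs = tuple(str(c) for c in row["coefficients"])
    n_expected = form.n_coefficients
    if len(coefs) != n_expected:
        raise SchemaError(
            f"entry ({row['scope']}, {row['compartment']}): {form.name.value} expects "
            f"{n_expected} coefficients, got {len(coefs)}"
        )
    if form.name in (ModelFormName.POWER, ModelFormName.POWER_MULTI) and float(coefs[0]) <= 0:
        raise SchemaError(
            f"entry ({row['scope']}, {row['compartment']}): power scale must be positive"
        )
    return RegistryEntry(
        scope=row["scope"],
        compartment=row["compartment"],
        form=form,
        coefficients=coefs,
        provenance=row.get("provenance", "user"),
        cf=row.get("cf"),
        fit_digits=dict(row.get("fit", {})),
        units=dict(row.get("units", _DEFAULT_UNITS)),
        builtin=builtin,
    )


class SchemaError(ValueError):
    """Registry document violates the schema."""


class MissingModelError(KeyError):
    """Requested (scope, compartment) key is not in the registry."""


class ModelRegistry:
    """Lookup table of allometric equations keyed by (scope, compartment).

    Built-in published entries are immutable; user documents may only add
    new keys (typically the AGB equations).
    """

    def __init__(self, entries: list[RegistryEntry]):
        self._entries: dict[tuple[str, str], RegistryEntry] = {}
        for e in entries:
            if e.key in self._entries:
                raise SchemaError(f"duplicate registry key {e.key}")
            self._entries[e.key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def keys(self):
        return self._entries.keys()

    def entry(self, scope: str, compartment: Compartment) -> RegistryEntry:
        key = (str(scope), compartment)
        if key not in self._entries:
            available = sorted(self._entries.keys())
            raise MissingModelError(
                f"no model for {key}; available keys: {available}"
            )
        return self._entries[key]

    def get_model(self, scope: str, compartment: Compartment) -> AllometricModel:
        """The published equation for a (height class | GENERALIST, compartment)."""
        return self.entry(scope, compartment).model()

    def add(self, row: dict) -> None:
        entry = _entry_from_row(row, builtin=False)
        if entry.key in self._entries and self._entries[entry.key].builtin:
            raise SchemaError(f"cannot override built-in entry {entry.key}")
        if entry.key in self._entries:
            raise SchemaError(f"duplicate registry key {entry.key}")
        self._entries[entry.key] = entry

    def save(self, path) -> None:
        """Write user (non-built-in) entries as a JSON document."""
        doc = {"entries": [e.to_json() for e in self if not e.builtin]}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    def to_document(self) -> dict:
        return {"entries": [e.to_json() for e in self]}


def builtin_registry() -> ModelRegistry:
    """Registry holding exactly the published coefficient sets (16 entries)."""
    return ModelRegistry([_entry_from_row(r, builtin=True) for r in _BUILTIN_ROWS])


def load_registry(source=None) -> ModelRegistry:
    """Built-ins merged with an optional user JSON document.

    ``source`` may be a path or an already-parsed dict with an "entries"
    list. User entries may add keys (e.g. per-class AGB equations with a
    correction factor) but never replace a built-in.
    """
    reg = builtin_registry()
    if source is None:
        return reg
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if not isinstance(doc, dict) or not isinstance(doc.get("entries", []), list):
        raise SchemaError('/: registry document must be {"entries": [...]}')
    for i, row in enumerate(doc.get("entries", [])):
        required = {"scope", "compartment", "form", "predictors", "coefficients"}
        missing = required - set(row)
        if missing:
            raise SchemaError(f"/entries/{i}: missing fields {sorted(missing)}")
        if row["compartment"] not in COMPARTMENTS:
            raise SchemaError(f"/entries/{i}/compartment: unknown {row['compartment']!r}")
        reg.add(row)
    return reg


# digit checksum of the built-in coefficient strings, used to detect any
# accidental edit of the published values
_BUILTIN_CHECKSUM = None


def _checksum(reg: ModelRegistry) -> int:
    import zlib

    payload = "|".join(
        ";".join((e.scope, e.compartment, e.form.name.value) + e.coefficients)
        for e in sorted(reg, key=lambda e: e.key)
        if e.builtin
    )
    return zlib.crc32(payload.encode())


def validate_registry(reg: ModelRegistry) -> dict:
    """Arity/positivity checks plus a digit-exact check of the built-ins.

    Returns a report dict {"ok", "n_entries", "n_builtin", "problems"}.
    """
    global _BUILTIN_CHECKSUM
    if _BUILTIN_CHECKSUM is None:
        _BUILTIN_CHECKSUM = _checksum(builtin_registry())
    problems: list[str] = []
    n_builtin = 0
    for e in reg:
        if e.builtin:
            n_builtin += 1
        if len(e.coefficients) != e.form.n_coefficients:
            problems.append(f"{e.key}: arity mismatch")
        if e.form.name in (ModelFormName.POWER, ModelFormName.POWER_MULTI):
            if float(e.coefficients[0]) <= 0:
                problems.append(f"{e.key}: non-positive power scale")
    if _checksum(reg) != _BUILTIN_CHECKSUM:
        problems.append("built-in entries do not match the published digits")
    return {"ok": not problems, "n_entries": len(reg), "n_builtin": n_builtin, "problems": problems}
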
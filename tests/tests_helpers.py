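"""Shared helpers for the test suite."""

from mangrove_allometry.synthetic_data import simulate_root_fit_data


def root_fit_frame(registry, cls: str, comp: str, n: int, cv: float, seed: int):
    """(basal diameter, dry mass) pairs for one per-class root equation,
    constant-variance noise (the convention the fitted equations assume)."""
    return simulate_root_fit_data(registry, cls, comp, n=n, cv=cv, seed=seed, noise="additive")
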
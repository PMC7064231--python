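"""Reconstruct per-tree below-ground biomass for the simulated population:
measured (excavated) roots + model-predicted unexcavated roots + root crown.

Reads results/simulated/ (run 01 first), writes results/reconstructed/tree_bgb.csv
and prints per-class compartment shares.
"""

from pathlib import Path

import pandas as pd

from mangrove_allometry.carbon_stand import compartment_shares
from mangrove_allometry.mensuration import HeightClass, read_tree_inventory
from mangrove_allometry.published_models import builtin_registry
from mangrove_allometry.root_reconstruction import (
    RootType,
    estimate_unexcavated,
    read_root_crowns,
    read_root_samples,
    total_root_mass,
    tree_bgb,
)

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "reconstructed"


def main() -> None:
    trees = read_tree_inventory(SIM / "trees.csv")
    samples = read_root_samples(SIM / "root_samples.csv")
    crowns = {c.tree_id: c for c in read_root_crowns(SIM / "root_crowns.csv")}
    registry = builtin_registry()
    models = {
        (cls, rt): registry.get_model(cls.value, f"UNEXCAVATED_{rt.value}")
        for cls in HeightClass
        for rt in RootType
    }
    filled = estimate_unexcavated(samples, models, {t.tree_id: t.height_class for t in trees})
    rows = []
    for t in trees:
        mine = [s for s in filled if s.tree_id == t.tree_id]
        ledger = tree_bgb(
            crowns[t.tree_id],
            primary_kg=total_root_mass(mine, RootType.PRIMARY),
            secondary_kg=total_root_mass(mine, RootType.SECONDARY),
        )
        rows.append(
            {
                "tree_id": t.tree_id,
                "height_class": t.height_class.value,
                "crown_kg": ledger.crown_kg,
                "primary_kg": ledger.primary_kg,
                "secondary_kg": ledger.secondary_kg,
                "total_kg": ledger.total_kg,
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "tree_bgb.csv", index=False)
    print(f"{len(df)} trees reconstructed -> {OUT / 'tree_bgb.csv'}")
    for cls, grp in df.groupby("height_class"):
        shares = compartment_shares(
            {"crown": grp.crown_kg.sum(), "roots": (grp.primary_kg + grp.secondary_kg).sum()}
        )
        print(
            f"  {cls}: mean BGB {grp.total_kg.mean():.3f} kg/tree, "
            f"crown {shares['crown']:.1f}% / roots {shares['roots']:.1f}%"
        )


if __name__ == "__main__":
    main()
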
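"""Generate the synthetic study population: 45 trees in three height
strata (15 each), each with a root system in which exactly two primary
roots (plus their secondaries) are excavated.

Writes trees.csv, root_samples.csv, root_crowns.csv under results/simulated/.
"""

from pathlib import Path

from mangrove_allometry.mensuration import write_tree_inventory
from mangrove_allometry.root_reconstruction import write_root_crowns, write_root_samples
from mangrove_allometry.synthetic_data import SimulationConfig, simulate_root_system, simulate_trees

import numpy as np

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    trees = simulate_trees(cfg)
    rng = np.random.default_rng(SEED + 1)
    samples, crowns = [], []
    for tree in trees:
        s, c = simulate_root_system(tree, cfg, rng=rng)
        samples.extend(s)
        crowns.append(c)
    OUT.mkdir(parents=True, exist_ok=True)
    write_tree_inventory(trees, OUT / "trees.csv")
    write_root_samples(samples, OUT / "root_samples.csv")
    write_root_crowns(crowns, OUT / "root_crowns.csv")
    by_class = {c: sum(1 for t in trees if t.height_class.value == c) for c in ("C1", "C2", "C3")}
    n_exc = sum(1 for s in samples if s.excavated)
    print(f"seed {SEED}: {len(trees)} trees {by_class}, {len(samples)} roots "
          f"({n_exc} excavated) -> {OUT}")


if __name__ == "__main__":
    main()
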
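#!/usr/bin/env python
"""Generate the synthetic study world and write its input streams.

Produces the four inputs every later stage consumes — the monthly
NINO3.4-style index, the gridded monthly climate with its pixel geography,
and the child-level survey microdata — plus the ground-truth sidecar with
all planted parameters.  Raw data land under scratch/world/ (they are bulky
regeneratable artifacts); a compact summary of what was planted goes to
results/world_summary.csv.

Run:  python analysis/01_simulate_world.py [--seed 0] [--n-children 100000]
"""

import argparse
from pathlib import Path

import pandas as pd

from ensogrowth import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-children", type=int, default=100_000)
    args = ap.parse_args()

    cfg = syn.WorldConfig(seed=args.seed)
    world = syn.simulate_world(cfg, with_grid=True, n_children=args.n_children)

    out = ROOT / "scratch" / "world"
    out.mkdir(parents=True, exist_ok=True)
    world.nino.to_csv(out / "nino.csv", index=False)
    world.grid.write_csv(out / "grid_values.csv", out / "grid_pixels.csv")
    world.children.to_csv(out / "children.csv", index=False)
    syn.write_ground_truth(cfg, out / "ground_truth.json")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    betas = cfg.effects.outcome_betas
    summary = pd.DataFrame(
        {
            "quantity": [
                "n_children",
                "n_tropical_years",
                "n_countries",
                "n_teleconnected_countries",
                "n_positive_precip_admins",
                "planted_beta_n_waz",
                "planted_interaction_waz",
                "index_yearly_sd",
            ],
            "value": [
                len(world.children),
                cfg.n_years,
                cfg.n_countries,
                len(world.truth["teleconnected_countries"]),
                len(world.truth["positive_precip_admins"]),
                betas["waz"][0],
                betas["waz"][1] - betas["waz"][0],
                world.nino.groupby("year")["value"].mean().std(),
            ],
        }
    )
    summary.to_csv(results / "world_summary.csv", index=False)
    print(f"world written to {out} ({len(world.children)} children, "
          f"{world.grid.n_pixels} pixels, {cfg.n_years} years)")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
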
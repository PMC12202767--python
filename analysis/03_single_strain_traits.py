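#!/usr/bin/env python
"""Isolation traits: chemotactic indices, growth rates, metabolite roles.

For every strain x metabolite the script computes the chemotactic index
(with the attraction t-test against 1) and the maximum specific growth
rate (sliding log-linear window, growth t-test against 0), combines both
into signal/substrate role calls and tallies the role categories across
the assay grid.
"""
from pathlib import Path

import pandas as pd

from hotspot_assembly import RunConfig, compute_ic
from hotspot_assembly.chemotaxis import write_ic_table
from hotspot_assembly.classification import classify_role, tally_roles
from hotspot_assembly.growth import estimate_rates_table, write_rates_table
from hotspot_assembly.tables_io import read_growth_table, read_isca_table


def main() -> None:
    data = Path("results/data")
    out = Path("results")
    config = RunConfig()

    isca = read_isca_table(data / "isca_counts.csv")
    estimates = [compute_ic(sub, config) for _, sub in isca.experiments()]
    write_ic_table(estimates, out / "ic_table.csv")

    rates = estimate_rates_table(read_growth_table(data / "growth_curves.csv"), config)
    write_rates_table(rates, out / "rates.csv")

    solo = {(e.strain_set[0], e.chemoattractant): e for e in estimates}
    rate_map = {(r.strain_id, r.metabolite): r for r in rates}
    calls = [
        classify_role(solo[key], rate_map[key])
        for key in sorted(set(solo) & set(rate_map))
    ]
    pd.DataFrame(
        [
            {
                "strain_id": c.strain_id,
                "metabolite": c.metabolite,
                "is_signal": c.is_signal,
                "is_substrate": c.is_substrate,
                "role": c.role,
            }
            for c in calls
        ]
    ).to_csv(out / "roles.csv", index=False)

    n_attract = sum(e.attracted for e in estimates)
    n_grew = sum(r.grew for r in rates)
    print(f"scored {len(calls)} strain x metabolite assays: "
          f"{n_attract} attractions, {n_grew} significant growth responses")
    tally = tally_roles(calls)
    for role in ("both", "signal", "substrate", "none"):
        print(f"  {role:>9}: {tally.counts[role]:2d} "
              f"({tally.percentages[role]}%)")


if __name__ == "__main__":
    main()
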
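#!/usr/bin/env python
"""Recompute the published cohort-summary statistics from printed counts.

Checks the φ/χ² machinery against every binary row of the published cohort
table and prints the mortality bookkeeping. Writes results/published_phi.csv.
"""

from pathlib import Path

from hemotrace import experiments as ex
from hemotrace import published

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = ex.phi_recomputation()
    table["match"] = table["phi_computed"] == table["phi_printed"]
    table.to_csv(OUT / "published_phi.csv", index=False)
    m = published.mortality_table()
    print(f"1-year mortality: {m['n_died']}/{m['n_total']} = {ex.mortality_percent():.2f}%")
    print(table.to_string(index=False))
    n_match = int(table["match"].sum())
    print(
        f"\n{n_match}/{len(table)} printed |φ| values reproduce to 2 decimals "
        "(the male row prints 0.13 but recomputes to 0.12 from its own counts)."
    )


if __name__ == "__main__":
    main()
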
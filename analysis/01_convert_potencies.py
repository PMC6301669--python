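#!/usr/bin/env python
"""Convert the measured powder mass potencies to molecular molar potencies.

Loads the packaged 31-compound table (30 powders + water, mass HU potency
at 80/100/120/140 kV), converts each row to molar potency via
p = eta * (1000/998) * molar mass, and writes both tables to results/.
"""

from pathlib import Path

import pandas as pd

import hupotency as hp

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = hp.load_powder_table()
    H = hp.compound_potency_matrix(table)

    RESULTS.mkdir(exist_ok=True)
    table.to_frame().to_csv(RESULTS / "mass_potency_table.csv")
    H.to_csv(RESULTS / "compound_molar_potency.csv")

    print(f"{len(table)} compounds at voltages {table.voltages} kV")
    water = hp.compound_molar_potency(table["water"])
    print(f"water molar potency at 80 kV: {water[80.0]:.6f} AHU m^3/mol")
    print(f"molar potency range at 80 kV: "
          f"{H[80.0].min():.4f} ({H[80.0].idxmin()}) .. "
          f"{H[80.0].max():.4f} ({H[80.0].idxmax()})")
    print(f"wrote {RESULTS / 'compound_molar_potency.csv'}")


if __name__ == "__main__":
    main()
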
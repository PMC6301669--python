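#!/usr/bin/env python
"""Recover mass potency from simulated bottle scans via the weighed mass.

Simulates CT volumes of a powder-filled cylindrical bottle (known mass
potency, 5 HU noise, blurred walls), segments bottle-plus-skirt by
threshold, subtracts an empty-bottle scan, and recovers eta from
eta = rho_water * net integral(mu*) / mass.  Also reports the sensitivity
of the estimate to the segmentation threshold over a 40 HU range.
"""

from pathlib import Path

import pandas as pd

import hupotency as hp

RESULTS = Path(__file__).resolve().parents[1] / "results"

GEOMETRY = hp.CylinderSpec(
    center=(8e-3, 8e-3, 8e-3), radius=4e-3, height=10e-3, wall_thickness=1e-3
)
SHAPE = (64, 64, 32)
SPACING = (0.25e-3, 0.25e-3, 0.5e-3)
FILL_DENSITY = 1200.0  # kg/m^3, a typical packed-powder density
THRESHOLD = -800.0  # HU; captures the bottle plus its blurred skirt


def main() -> None:
    rows = []
    for eta_true in (0.9, 1.0, 1.5, 2.0):
        phantom = hp.simulate_bottle_volume(
            SHAPE, SPACING, GEOMETRY,
            mu_star_fill=eta_true * FILL_DENSITY / hp.WATER_DENSITY,
            mu_star_wall=1.0, noise_sd_hu=5.0, seed=10, blur_sigma_vox=1.0,
        )
        empty = hp.simulate_bottle_volume(
            SHAPE, SPACING, GEOMETRY,
            mu_star_fill=0.0, mu_star_wall=1.0, noise_sd_hu=5.0, seed=11,
            blur_sigma_vox=1.0,
        )
        mass = FILL_DENSITY * phantom.fill_volume
        seg_empty = hp.segment_bottle(empty.volume, THRESHOLD)
        eta = hp.potency_from_mass(
            hp.segment_bottle(phantom.volume, THRESHOLD), seg_empty, mass
        )
        sensitivity = hp.threshold_sensitivity(
            phantom.volume, seg_empty, mass, center=THRESHOLD, full_range=40.0
        )
        rows.append({
            "eta_true": eta_true,
            "eta_recovered": eta,
            "relative_error": abs(eta - eta_true) / eta_true,
            "threshold_sensitivity_40HU": sensitivity,
        })

    frame = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "bottle_recovery.csv", index=False)
    print(frame.round(5).to_string(index=False))
    print(f"max relative error: {frame.relative_error.max():.2%}; "
          f"max threshold sensitivity: "
          f"{frame.threshold_sensitivity_40HU.max():.2%} over a 40 HU range")


if __name__ == "__main__":
    main()
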
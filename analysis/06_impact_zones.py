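#!/usr/bin/env python
"""Transmission-loss and impact-zone arithmetic for mitigation scenarios.

Tabulates effect radii and affected-area ratios for deterrence source
levels under the fitted spherical spreading model (1.5 dB/km
absorption), including the headline mitigation results: the factor-9
TTS-area reduction from a 10-dB source cut and the < 5% residual
affected area from a 26-dB cut.  Writes impact_zones.csv.
"""

import argparse
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ahdtag import reference
from ahdtag.tracking import (
    PropagationModel,
    impact_area_ratio,
    predicted_response_threshold,
    received_level,
    solve_effect_range,
    transmission_loss,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()
    os.makedirs(args.out, exist_ok=True)

    sph = PropagationModel("spherical", 1.5)
    sph0 = PropagationModel("spherical", 0.0)
    thr = predicted_response_threshold(
        reference.HEARING_THRESHOLD_14KHZ, reference.SENSATION_LEVEL_RESPONSE
    )
    print(f"predicted behavioural response threshold: {thr:.0f} dB re 1 uPa")

    tl = transmission_loss(1000.0, sph)
    print(f"TL at 1 km (spherical + 1.5 dB/km): {tl:.1f} dB -> rounds to {round(tl)}")
    print(f"RL at 1 km from a {reference.REDUCED_SL:.0f} dB source: "
          f"{reference.REDUCED_SL - round(tl):.0f} dB re 1 uPa")

    rows = []
    for sl in (reference.FULL_SL, 180.0, 176.0, reference.REDUCED_SL):
        for threshold in (reference.RESPONSE_RL_THRESHOLD, 110.0):
            radius = solve_effect_range(sl, threshold, sph)
            rows.append({
                "source_level_db": sl,
                "rl_threshold_db": threshold,
                "model": "spherical+1.5dB/km",
                "effect_radius_km": round(radius / 1000, 2),
                "area_vs_sl190_pct": round(
                    100 * impact_area_ratio(
                        radius, solve_effect_range(reference.FULL_SL, threshold, sph)
                    ), 2),
            })
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(args.out, "impact_zones.csv"), index=False)
    print(table.to_string(index=False))

    r1_km = reference.TTS_RADIUS_KM["HP1"]
    rl_edge = received_level(reference.AHD_SOURCE_LEVEL, r1_km * 1000, sph0)
    r2_km = round(
        solve_effect_range(reference.AHD_SOURCE_LEVEL - 10, rl_edge, sph0) / 1000, 1
    )
    print(f"\n10-dB source cut: TTS radius {r1_km} km -> {r2_km} km "
          f"(area factor {impact_area_ratio(r1_km, r2_km):.0f})")


if __name__ == "__main__":
    main()
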
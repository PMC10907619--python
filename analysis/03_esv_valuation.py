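"""Dynamically corrected ecosystem-service valuation.

Computes the correction factors (biomass Q, social development PI) from
the synthetic series, values both epochs of the synthetic region under
the epoch-appropriate equivalent-table version, maps the per-cell value
raster into five natural-breaks levels, and finally pushes the study's
printed endpoint totals through the same reporting arithmetic
(increments, % changes, contribution shares).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from esvopt import accounting as acct
from esvopt import valuation as val
from esvopt.grids import read_ascii_grid, write_ascii_grid
from esvopt.pipeline import report_consistency
from esvopt.synthetic import SocioSeries

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_series() -> dict[str, SocioSeries]:
    df = pd.read_csv(ROOT.parent / "scratch" / "synthetic" / "series.csv", index_col="year")
    return {c: SocioSeries(c, list(df.index), list(df[c])) for c in df.columns}


def main() -> None:
    series = load_series()
    year = 2020
    Q = val.biomass_factor(val.BiomassCorrection(
        series["npp_region"].value_at(year), series["npp_nation"].value_at(year),
        series["fvc_region"].value_at(year), series["fvc_nation"].value_at(year)))
    PI = val.social_coefficient(val.SocialCorrection(
        series["gdp_region"].value_at(year), series["gdp_nation"].value_at(year),
        series["engel_region"].value_at(year), series["engel_nation"].value_at(year)))
    Ea = val.standard_equivalent(series, year)
    print(f"corrections for {year}: Ea={Ea:.0f} yuan/hm2, Q={Q:.3f}, "
          f"PI={PI:.3f}")

    frames = []
    for epoch in ("1990", "2020"):
        grid = read_ascii_grid(ROOT.parent / "scratch" / "synthetic" / f"lulc_{epoch}.asc")
        eq = val.load_equivalent_table(val.table_version_for_year(int(epoch)))
        ea_epoch = val.standard_equivalent(series, int(epoch))
        vc = val.corrected_coefficients(eq, ea_epoch, Q, PI)
        at = acct.class_areas(grid, epoch)
        rep = val.esv_total(at, vc, eq.categories)
        frames.append(rep.to_frame())
        print(f"  {epoch}: table v{eq.version}, total "
              f"{rep.total / 1e6:.2f} million yuan "
              f"({len(eq.functions)} functions)")
        if epoch == "2020":
            raster = val.esv_grid(grid, val.class_coefficients(vc))
            levels, breaks = val.jenks_levels(raster, k=5)
            write_ascii_grid(ROOT.parent / "scratch" / "esv_levels_2020.asc", levels.astype(int),
                             nodata=0, cellsize=grid.cellsize)
            print(f"  five-level map breaks (yuan/hm2): "
                  f"{np.round(breaks, 1).tolist()}")
    pd.concat(frames, ignore_index=True).to_csv(
        ROOT / "synthetic_esv.csv", index=False)

    # the published endpoint totals through the same reporting arithmetic
    printed = {"1990": 18.62, "2020": 67.28}  # 10^9 yuan
    changes = report_consistency(printed)
    grass_water = val.contribution_share(30.64 + 14.61,
                                         val.increment(18.62, 67.28))
    changes.to_csv(ROOT / "published_esv_changes.csv", index=False)
    print(f"published endpoints: increment "
          f"{changes['increment'].iloc[0]:.2f} billion yuan; grassland+water "
          f"contribution {grass_water:.0f}% of the increase")
    scen = report_consistency(
        {"2020": 67.28, "bau": 68.83, "red": 64.47, "elp": 67.99,
         "eeb": 66.79})
    scen.to_csv(ROOT / "published_scenario_changes.csv", index=False)
    print("published 2035 scenarios vs 2020:")
    print(scen.to_string(index=False))


if __name__ == "__main__":
    main()
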
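"""Treatment and depth statistics on the simulated dataset.

One-way ANOVA + LSD compact letters per index across warming treatments,
and the balanced two-way warming x soil-layer ANOVA on per-sample density
(individuals per 100 g dry soil), whose degrees of freedom reproduce the
5 x 5 x 3 design structure (4, 4, 16, 50; corrected total 74).
"""
from pathlib import Path

import numpy as np

from nemafauna import (default_taxonomy, read_community, sample_density,
                       two_way_anova_balanced)
from nemafauna.groupstats import write_anova_report

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main():
    matrix = read_community(DATA / "counts.csv", DATA / "metadata.csv",
                            default_taxonomy())
    treatments = list(dict.fromkeys(s.treatment for s in matrix))
    layers = list(dict.fromkeys(s.depth_layer for s in matrix))
    reps = sorted({s.replicate for s in matrix})
    cube = np.full((len(treatments), len(layers), len(reps)), np.nan)
    for s in matrix:
        cube[treatments.index(s.treatment), layers.index(s.depth_layer),
             reps.index(s.replicate)] = sample_density(s)

    result = two_way_anova_balanced(cube, "warming", "soil_layer")
    OUT.mkdir(parents=True, exist_ok=True)
    write_anova_report(result, OUT / "density_two_way_anova.csv")

    print("two-way ANOVA on nematode density (ind per 100 g dry soil):")
    print(result.to_frame().round(3).to_string(index=False))
    print(f"model R^2 = {result.r_squared:.3f}")
    layer_row = result.row("soil_layer")
    print(f"\nsoil layer effect: F = {layer_row.f:.1f}, p = {layer_row.p:.2g} "
          "(depth drives density in the simulated design, as in the field)")


if __name__ == "__main__":
    main()
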
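"""Place each treatment on the enrichment/structure faunal profile.

Mean EI and SI per treatment from the per-sample index table, quadrant
assignment by the 50/50 split, and a quadrant scatter written under
scratch/ (plot output is disposable).
"""
from pathlib import Path

import pandas as pd

from nemafauna import faunal_profile_quadrant

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

QUADRANT_MEANING = {
    "A": "enriched, disturbed (nutrient-rich, low structure)",
    "B": "enriched and structured (maturing food web)",
    "C": "structured, resource-limited",
    "D": "basal, depleted",
}


def main():
    summary = pd.read_csv(OUT / "indices_per_treatment.csv")
    ei = summary.query("index == 'EI'").set_index("treatment")["mean"]
    si = summary.query("index == 'SI'").set_index("treatment")["mean"]

    rows = []
    for t in ei.index:
        quadrant, boundary = faunal_profile_quadrant(ei[t], si[t])
        rows.append({"treatment": t, "EI": ei[t], "SI": si[t],
                     "quadrant": quadrant, "on_boundary": boundary})
        print(f"{t:>3}: EI = {ei[t]:5.1f}, SI = {si[t]:5.1f} -> "
              f"quadrant {quadrant} ({QUADRANT_MEANING[quadrant]})")
    pd.DataFrame(rows).to_csv(OUT / "faunal_profile.csv", index=False)

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.axhline(50, color="grey", lw=0.8)
        ax.axvline(50, color="grey", lw=0.8)
        ax.scatter(ei, si)
        for t in ei.index:
            ax.annotate(t, (ei[t], si[t]), textcoords="offset points",
                        xytext=(4, 4))
        ax.set(xlim=(0, 100), ylim=(0, 100),
               xlabel="Enrichment index (EI)", ylabel="Structure index (SI)")
        scratch = ROOT / "scratch"
        scratch.mkdir(exist_ok=True)
        fig.savefig(scratch / "faunal_profile.png", dpi=150)
        print(f"scatter written to {scratch / 'faunal_profile.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the scatter")


if __name__ == "__main__":
    main()
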
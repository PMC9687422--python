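"""Generate the synthetic warming-gradient dataset used by the later steps.

Emulates the field design: 5 treatments (CK, A-D) x 3 replicate plots x
5 depth layers, surface-aggregated density, treatment-specific trophic
composition and soil moisture.  Writes the counts/metadata CSV pair under
results/data/.
"""
from pathlib import Path

from nemafauna import SimConfig, generate_dataset, write_community

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 42


def main():
    cfg = SimConfig()
    matrix = generate_dataset(cfg, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    write_community(matrix, OUT / "counts.csv", OUT / "metadata.csv")
    cfg.to_file(OUT / "sim_config.yaml")

    total = sum(s.total for s in matrix)
    print(f"wrote {len(matrix)} samples (seed {SEED}) to {OUT}")
    print(f"total individuals: {total}")
    by_layer = {}
    for s in matrix:
        by_layer[s.depth_layer] = by_layer.get(s.depth_layer, 0) + s.total
    print("individuals per layer (surface aggregation):")
    for layer, n in by_layer.items():
        print(f"  {layer:>6} cm: {n}")


if __name__ == "__main__":
    main()
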
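"""Decode food level from lifespan alone, via per-food Weibull fits.

Asks whether the physiological output (lifespan) carries a comparable amount
of food information to the gene-expression readouts, and how the mutants
degrade it. Writes matrices to results/decoding/.
"""

from pathlib import Path

import pandas as pd

import foodcode as fc
from foodcode import pipeline

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results" / "decoding"
GENOTYPES = ("wildtype", "tph1_null", "daf7_null", "double_null")
SEED = 20260929

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for genotype in GENOTYPES:
        life = pipeline.read_lifespan_csv(DATA / f"lifespan_{genotype}.csv")
        res = fc.crossval_decode(life, readout="lifespan", k=5, seed=SEED)
        res.to_frames()["ml_matrix"].to_csv(OUT / f"{genotype}_lifespan_ml.csv")
        rows.append({"genotype": genotype, "accuracy": res.overall_accuracy,
                     "above_chance": res.accuracy_above_chance})
        print(f"  {genotype:12s} lifespan decoding accuracy {res.overall_accuracy:.3f} "
              f"({res.accuracy_above_chance:+.3f} above chance)")
    pd.DataFrame(rows).to_csv(OUT / "lifespan_accuracy.csv", index=False)
    print(f"tables in {OUT}")

if __name__ == "__main__":
    main()
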
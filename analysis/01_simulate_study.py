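"""Simulate the serum pre-storage handling study and write the CSV pair.

19 donors x 13 aliquots (reference, 9 handling conditions, 3 freeze-thaw),
plus 5 pool and 3 zero samples on each of 4 plates.
"""
from pathlib import Path

from serumqc import GeneratorConfig, generate_study, write_dataset

OUT = Path("results/analysis")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = generate_study(GeneratorConfig(seed=seed))
    write_dataset(ds, OUT / "concentrations.csv", OUT / "samples.csv")
    roles = ds.sheet["role"].value_counts().to_dict()
    print(f"simulated {len(ds.values)} samples x {len(ds.panel)} metabolites: {roles}")


if __name__ == "__main__":
    main()
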
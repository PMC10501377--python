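#!/usr/bin/env python
"""Simulate the case-control screening study.

Generates the default synthetic dataset (4 contaminated + 4 reference
pools, triplicate injections, a procedural blank pool, 500 matrix
features, planted PFSA/FASA/Cl-PFSA/FASA-PrA homologous series; seed 42)
and writes the observation table, MS/MS spectra and ground truth under
results/simulated/.
"""

from pathlib import Path

from pfasnta import io as pio
from pfasnta.synthetic import GeneratorConfig, generate_dataset

OUT = Path("results/simulated")


def main(seed: int = 42) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(GeneratorConfig(), seed=seed)
    pio.write_feature_observations(ds.observations, OUT / "observations.csv")
    pio.write_spectra(ds.spectra, OUT / "spectra.mgf")
    ds.truth.to_csv(OUT / "truth.csv", index=False)
    n_pfas = (ds.truth.kind == "pfas").sum()
    print(f"wrote {len(ds.observations)} observations "
          f"({n_pfas} planted PFAS features, "
          f"{(ds.truth.kind == 'matrix').sum()} matrix, "
          f"{(ds.truth.kind == 'blank').sum()} blank-derived) -> {OUT}")


if __name__ == "__main__":
    main()
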
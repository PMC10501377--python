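#!/usr/bin/env python
"""Detect CF2 homologous series among the prioritized features.

Reproduces the KMD-plot reading: members of a homologous series share a
Kendrick mass defect and differ by integer CF2 units, with retention time
increasing along the chain. Writes the series table and KMD-plot export
under results/homologues/.
"""

from pathlib import Path

import pandas as pd

from pfasnta import io as pio
from pfasnta.chem import kendrick
from pfasnta.homologue import detect_series, series_rt_consistency
from pfasnta.pipeline import AlignedFeature

PRI = Path("results/prioritized")
OUT = Path("results/homologues")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(PRI / "survivors.csv")
    feats = [
        AlignedFeature(feature_id=r.feature_id, mz=r.mz, rt=r.rt_min,
                       intensities={}, kendrick=kendrick(r.mz))
        for r in df.itertuples(index=False)
    ]
    series = detect_series(feats, "CF2", kmd_tol=0.005, mz_tol=0.01, min_members=2)
    print(f"{len(series)} homologous series among {len(feats)} prioritized features")
    for s in series:
        ok = series_rt_consistency(s, feats, slack=0.05)
        mzs = ", ".join(f"{m:.4f}" for m in s.member_mz)
        print(f"  {s.series_id}: {len(s)} members, mean KMD {s.mean_kmd:+.4f}, "
              f"RT-consistent={ok}  [{mzs}]")
    pio.write_series_report(series, OUT / "series.csv")
    pio.write_kmd_plot_data(feats, series, OUT / "kmd_plot.csv")


if __name__ == "__main__":
    main()
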
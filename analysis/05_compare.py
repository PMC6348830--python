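"""Compare scaled animal TIACs with the human reference from the same run.

For every (species, region, method) row the report gives the ratio to the
human TIAC, flagged as under- or over-estimation, with the display-rounded
factor. Results go to results/report.csv.
"""

from pathlib import Path

import pandas as pd

from biokin.cli import _load_tiacs
from biokin.curves import write_report
from biokin.xscale import ScaledTIAC, compare

OUT = Path("results")


def main() -> None:
    sdf = pd.read_csv(OUT / "scaled.csv")
    scaled = [
        ScaledTIAC(
            method=int(r.method), source_species=str(r.species), region=str(r.region),
            value=float(r.value), unit=str(r.unit),
        )
        for r in sdf.itertuples()
        if pd.notna(r.value)
    ]
    human_ref = [t for t in _load_tiacs(OUT / "tiacs.csv") if t.species == "human"]
    report = compare(scaled, human_ref)
    write_report(report, OUT / "report.csv", format="csv")

    df = report.to_frame()
    best = (
        df[df.region != "blood"]
        .assign(dev=lambda d: abs(d.ratio - 1))
        .sort_values("dev")
        .groupby(["species", "region"])
        .first()
    )
    print(df.drop(columns="unit").to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print("\nclosest method per organ (smallest deviation from the human TIAC):")
    print(best[["method", "ratio"]].to_string(float_format=lambda v: f"{v:.3g}"))
    print(f"\nwrote report to {OUT / 'report.csv'}")


if __name__ == "__main__":
    main()
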
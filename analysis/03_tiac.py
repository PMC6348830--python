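"""Integrate the selected fits into TIACs with propagated uncertainties.

The closed-form integral of each fitted model over [0, inf) gives the
time-integrated activity coefficient; the standard error follows from
delta-method propagation of the fit covariance. Results go to
results/tiacs.csv.
"""

from pathlib import Path

import pandas as pd

from biokin.pipeline import fits_from_json
from biokin.tiac import integrate_tiac

OUT = Path("results")


def main() -> None:
    fits = fits_from_json(OUT / "fits.json")
    rows = []
    for f in fits:
        est = integrate_tiac(f)
        unit = "h/mL" if est.unit == "h_per_ml" else "h"
        print(f"{f.group:16s} TIAC = {est.value:10.4g} +/- {est.se:.2g} {unit}")
        rows.append(
            {
                "species": est.species,
                "region": est.region,
                "tiac": repr(float(est.value)),
                "se": repr(float(est.se)),
                "unit": est.unit,
            }
        )
    pd.DataFrame(rows, columns=["species", "region", "tiac", "se", "unit"]).to_csv(
        OUT / "tiacs.csv", index=False, encoding="utf-8"
    )
    print(f"\nwrote {len(rows)} TIACs to {OUT / 'tiacs.csv'}")


if __name__ == "__main__":
    main()
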
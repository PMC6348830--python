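"""Extrapolate the animal TIACs to human by the five scaling methods.

Applies the same-biodistribution, relative-mass, time, combined and
allometric methods to the fitted mouse and pig results, using the
packaged species profiles. Mouse blood is excluded (no blood-volume
datum) and allometric scaling is skipped for blood (no exponent).
Results go to results/scaled.csv.
"""

from pathlib import Path

from biokin.cli import _load_tiacs
from biokin.curves import default_profiles
from biokin.pipeline import fits_from_json, table_reproduction

OUT = Path("results")


def main() -> None:
    tiacs = _load_tiacs(OUT / "tiacs.csv")
    fits = fits_from_json(OUT / "fits.json")
    profiles = default_profiles()
    # mouse blood has no volume datum: refuse mass-based methods there
    tiacs = [t for t in tiacs if not (t.species == "mouse" and t.region == "blood")]
    df = table_reproduction(tiacs, profiles, fits=fits)
    printable = df.copy()
    printable["value"] = printable["value"].map(lambda v: f"{v:.4g}")
    print(printable.to_string(index=False))
    out = df.copy()
    out["value"] = out["value"].map(lambda v: repr(float(v)))
    out.to_csv(OUT / "scaled.csv", index=False, encoding="utf-8")
    print(f"\nwrote {len(df)} scaled TIACs to {OUT / 'scaled.csv'}")


if __name__ == "__main__":
    main()
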
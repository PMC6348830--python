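"""Desk-scale arithmetic on the published cohort TIACs.

Reproduces what can be reproduced from printed inputs alone: allometric
scaling (Method 5) of the mouse organ TIACs with the cohort body masses,
and the same-biodistribution comparison factors (mouse kidneys 4x and
liver 7x underestimated; pig kidneys 1.3x over- and liver 1.3x
underestimated). Methods 2-4 need organ masses and fitted rate constants
that were never printed, so they are reported n/a here.
Results go to results/published_scaling.csv.
"""

from pathlib import Path

from biokin.reference import COHORT_MASSES_KG, cohort_profile, reference_tiacs
from biokin.pipeline import table_reproduction
from biokin.xscale import compare, method1_same

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    tiacs = reference_tiacs()
    profiles = {sp: cohort_profile(sp) for sp in COHORT_MASSES_KG}
    df = table_reproduction(tiacs, profiles, methods=(1, 5))
    printable = df.copy()
    printable["value"] = printable["value"].map(lambda v: f"{v:.4g}")
    print("published-TIAC scaling (closed-form methods):")
    print(printable.to_string(index=False))
    out = df.copy()
    out["value"] = out["value"].map(lambda v: repr(float(v)))
    out.to_csv(OUT / "published_scaling.csv", index=False, encoding="utf-8")

    ref = {(t.species, t.region): t for t in tiacs}
    human = [ref[("human", "kidneys")], ref[("human", "liver")]]
    scaled = [
        method1_same(ref[(sp, region)])
        for sp in ("mouse", "pig")
        for region in ("kidneys", "liver")
    ]
    print("\nsame-biodistribution comparison factors vs the human cohort:")
    for row in compare(scaled, human).rows:
        print(
            f"  {row['species']:6s} {row['region']:8s} {row['direction']}-estimated "
            f"by a factor of {row['factor_rounded']:g}"
        )
    print(f"\nwrote {len(df)} rows to {OUT / 'published_scaling.csv'}")


if __name__ == "__main__":
    main()
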
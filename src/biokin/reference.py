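"""Published cohort reference values for the ¹⁷⁷Lu-OPS201 study species.

These are the printed inputs for desk-scale table arithmetic: Method-1
TIACs for kidneys, liver and blood of the mouse, pig and human cohorts,
and the cohort-mean whole-body masses.  Organ TIACs are in hours, blood
TIACs in h/mL (integral of the fraction of injected activity per mL of
blood).
"""

from __future__ import annotations

from .curves import SpeciesProfile
from .tiac import TIACEstimate

__all__ = [
    "REFERENCE_TIACS",
    "COHORT_MASSES_KG",
    "reference_tiacs",
    "human_reference",
    "cohort_profile",
]

#: (species, region) -> (TIAC, standard error, unit)
REFERENCE_TIACS: dict[tuple[str, str], tuple[float, float, str]] = {
    ("mouse", "kidneys"): (1.44, 8.5e-2, "h"),
    ("mouse", "liver"): (0.75, 4.1e-2, "h"),
    ("mouse", "blood"): (0.0370, 2.0e-3, "h_per_ml"),
    ("pig", "kidneys"): (7.67, 1.8e-1, "h"),
    ("pig", "liver"): (4.08, 9.4e-2, "h"),
    ("pig", "blood"): (0.0002, 3.4e-6, "h_per_ml"),
    ("human", "kidneys"): (5.85, 4.2e-1, "h"),
    ("human", "liver"): (5.32, 3.4e-1, "h"),
    ("human", "blood"): (0.0002, 8.2e-5, "h_per_ml"),
}

#: cohort-mean whole-body masses (kg): mice 26 g, pigs 28 kg, patients 61 kg
COHORT_MASSES_KG: dict[str, float] = {"mouse": 0.026, "pig": 28.0, "human": 61.0}


def reference_tiacs(species: str | None = None) -> list[TIACEstimate]:
    """Published Method-1 TIACs as TIACEstimate objects."""
    out = []
    for (sp, region), (value, se, unit) in REFERENCE_TIACS.items():
        if species is not None and sp != species:
            continue
        out.append(TIACEstimate(value=value, se=se, region=region, species=sp, unit=unit))
    return out


def human_reference() -> list[TIACEstimate]:
    """Human cohort TIACs used as the comparison reference."""
    return reference_tiacs("human")


def cohort_profile(species: str) -> SpeciesProfile:
    """Bare cohort profile (whole-body mass only; no printed organ masses)."""
    return SpeciesProfile(name=species, m_wb=COHORT_MASSES_KG[species])
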
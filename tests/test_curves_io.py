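"""Curve/profile I/O: parsing, sigma autofill, validation, round trips."""

import json
import textwrap

import pytest

from biokin.curves import (
    CurveInputError,
    DEFAULT_SIGMA_CV,
    ScalingSpec,
    TimeActivityCurve,
    TimeActivitySample,
    default_profiles,
    read_curves,
    read_scaling_spec,
    read_species_profiles,
    write_curves,
    write_report,
)
from biokin.tiac import TIACEstimate
from biokin.xscale import ScaledTIAC, compare


def write_csv(tmp_path, text, name="curves.csv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


def test_read_curves_groups_and_sorts(tmp_path):
    p = write_csv(
        tmp_path,
        """\
        species,region,time_h,value,unit,sigma
        human,kidneys,24,10.0,pct_ia,1.0
        human,kidneys,1,30.0,pct_ia,3.0
        human,kidneys,3,20.0,pct_ia,2.0
        """,
    )
    curves = read_curves(p)
    assert len(curves) == 1
    (c,) = curves
    assert c.species == "human" and c.region == "kidneys"
    assert list(c.t) == [1.0, 3.0, 24.0]
    assert list(c.y) == [30.0, 20.0, 10.0]


def test_missing_sigma_filled_at_ten_percent(tmp_path):
    p = write_csv(
        tmp_path,
        """\
        species,region,time_h,value,unit
        pig,liver,1,50,pct_ia
        pig,liver,24,20,pct_ia
        """,
    )
    (c,) = read_curves(p)
    assert c.samples[0].sigma == pytest.approx(DEFAULT_SIGMA_CV * 50)
    assert c.samples[0].sigma == 5.0


def test_duplicate_times_rejected_naming_group(tmp_path):
    p = write_csv(
        tmp_path,
        """\
        species,region,time_h,value,unit
        pig,liver,1,50,pct_ia
        pig,liver,1,49,pct_ia
        """,
    )
    with pytest.raises(CurveInputError, match="pig/liver"):
        read_curves(p)


@pytest.mark.parametrize("bad_row", ["pig,liver,-1,50,pct_ia", "pig,liver,2,-5,pct_ia"])
def test_negative_time_or_value_rejected(tmp_path, bad_row):
    p = write_csv(
        tmp_path,
        f"""\
        species,region,time_h,value,unit
        pig,liver,1,50,pct_ia
        {bad_row}
        """,
    )
    with pytest.raises(CurveInputError):
        read_curves(p)


def test_mixed_units_within_group_rejected(tmp_path):
    p = write_csv(
        tmp_path,
        """\
        species,region,time_h,value,unit
        pig,blood,1,0.5,pct_ia_per_ml
        pig,blood,2,0.3,pct_ia
        """,
    )
    with pytest.raises(CurveInputError, match="mixed units"):
        read_curves(p)


def test_unit_coercion_policy(tmp_path):
    p = write_csv(
        tmp_path,
        """\
        species,region,time_h,value,unit
        pig,blood,1,0.5,%IA/mL
        pig,blood,2,0.3,%IA/mL
        """,
    )
    with pytest.raises(CurveInputError):
        read_curves(p, unit_policy="strict")
    (c,) = read_curves(p, unit_policy="coerce")
    assert c.unit == "pct_ia_per_ml"


def test_write_read_round_trip_bit_identical(tmp_path):
    samples = tuple(
        TimeActivitySample(t, v, 0.1 * v)
        for t, v in [(0.5, 31.41592653589793), (2.0, 7.0 / 3.0), (50.0, 0.123456789012345)]
    )
    original = TimeActivityCurve("pig", "kidneys", "pct_ia", samples)
    path = tmp_path / "rt.csv"
    write_curves([original], path)
    (reread,) = read_curves(path)
    assert reread == original


def test_curve_invariants():
    s = lambda t: TimeActivitySample(t, 1.0, 0.1)
    with pytest.raises(CurveInputError):
        TimeActivityCurve("m", "r", "pct_ia", (s(1.0),))  # < 2 samples
    with pytest.raises(CurveInputError):
        TimeActivityCurve("m", "r", "pct_ia", (s(1.0), s(1.0)))  # not increasing
    with pytest.raises(CurveInputError):
        TimeActivitySample(1.0, 1.0, 0.0)  # sigma must be positive


def test_species_profiles_roundtrip_and_validation(tmp_path):
    p = tmp_path / "profiles.json"
    p.write_text(json.dumps({"mouse": {"m_wb": 0.026}}))
    profiles = read_species_profiles(p)
    assert profiles["mouse"].m_wb == 0.026
    assert profiles["mouse"].organ_mass("kidneys") is None  # valid; Method 2 refuses later

    p.write_text(json.dumps({"mouse": {"m_wb": 0.026, "organ_masses": {"liver": 0}}}))
    with pytest.raises(CurveInputError):
        read_species_profiles(p)

    p.write_text(json.dumps({"mouse": {"organ_masses": {"liver": 0.001}}}))
    with pytest.raises(CurveInputError, match="m_wb"):
        read_species_profiles(p)


def test_default_profiles_ship_cohort_masses():
    profiles = default_profiles()
    assert profiles["mouse"].m_wb == pytest.approx(0.026)
    assert profiles["pig"].m_wb == pytest.approx(28.0)
    assert profiles["human"].m_wb == pytest.approx(61.0)
    # mouse blood volume is deliberately unavailable
    assert profiles["mouse"].blood_volume_ml is None


def test_scaling_spec_validation(tmp_path):
    spec = ScalingSpec()
    assert spec.time_exponent == 0.25
    assert spec.allometric_b["liver"] == 0.92
    assert spec.allometric_b["kidneys"] == 0.85
    with pytest.raises(CurveInputError):
        ScalingSpec(time_exponent=-1)
    with pytest.raises(CurveInputError):
        ScalingSpec(allometric_b={"liver": 1.2})
    p = tmp_path / "scaling.json"
    p.write_text(json.dumps({"method": 5, "allometric_b": {"liver": 0.9}}))
    loaded = read_scaling_spec(p)
    assert loaded.method == 5 and loaded.allometric_b["liver"] == 0.9


def _tiny_report():
    scaled = [
        ScaledTIAC(method=m, source_species=sp, region=r, value=v)
        for m, sp, r, v in [
            (1, "mouse", "kidneys", 1.44),
            (1, "mouse", "liver", 0.75),
            (5, "mouse", "kidneys", 0.45),
            (5, "mouse", "liver", 0.40),
            (1, "pig", "kidneys", 7.67),
            (1, "pig", "liver", 4.08),
        ]
    ]
    ref = [
        TIACEstimate(5.85, 0.42, region="kidneys", species="human"),
        TIACEstimate(5.32, 0.34, region="liver", species="human"),
    ]
    return compare(scaled, ref)


def test_write_report_row_count_and_roundtrip(tmp_path):
    import pandas as pd

    report = _tiny_report()
    csv_path = tmp_path / "report.csv"
    write_report(report, csv_path, format="csv")
    df = pd.read_csv(csv_path)
    assert len(df) == 6  # 2 organs x 3 (species, method) combinations

    json_path = tmp_path / "report.json"
    write_report(report, json_path, format="json")
    with open(json_path) as fh:
        records = json.load(fh)
    assert records == report.to_frame().to_dict(orient="records")


def test_write_report_empty(tmp_path):
    from biokin.xscale import ComparisonReport

    path = tmp_path / "empty.csv"
    write_report(ComparisonReport(rows=()), path, format="csv")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("species,")
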
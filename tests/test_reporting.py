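"""Selectivity arithmetic, comparison statistics, pipeline runner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import rcfqnmr as rq
from rcfqnmr.reporting import SelectivityError, compare_to_reference, selectivity

FIG1_UHPLC = {"PS": 8.2, "PG": 5.26, "PSOH": 3.8, "PGOH": 2.9, "OTHER": 23.5 - 20.16}


def test_selectivity_worked_example():
    """Printed chromatography yields reproduce the printed selectivities."""
    assert selectivity(FIG1_UHPLC, ["PS", "PG"]) == pytest.approx(57.0, abs=1.0)
    assert selectivity(FIG1_UHPLC, ["PSOH", "PGOH"]) == pytest.approx(29.0, abs=1.0)


def test_selectivity_edge_groups():
    assert selectivity(FIG1_UHPLC, list(FIG1_UHPLC)) == pytest.approx(100.0)
    assert selectivity(FIG1_UHPLC, []) == 0.0
    with pytest.raises(SelectivityError):
        selectivity({"PS": 0.0}, ["PS"])


@given(st.lists(st.floats(0.01, 50), min_size=2, max_size=8), st.data())
def test_selectivity_partition_sums_to_100(values, data):
    yields = {f"C{i}": v for i, v in enumerate(values)}
    split = data.draw(st.integers(1, len(values) - 1))
    keys = list(yields)
    total = selectivity(yields, keys[:split]) + selectivity(yields, keys[split:])
    assert total == pytest.approx(100.0, abs=0.01)


def _long(table):
    rows = [(s, c, y) for (s, c), y in table.items()]
    return pd.DataFrame(rows, columns=["sample", "compound", "yield_wt_pct"])


def test_compare_identity():
    tbl = {(s, c): y for s in "abc" for c, y in (("PS", 8.0), ("PG", 5.0))}
    rep = compare_to_reference(_long(tbl), _long(tbl))
    assert (rep.per_compound["r2_identity"] == 1.0).all()
    assert rep.mean_absolute_deviation == 0.0
    assert rep.mean_relative_deviation_pct == 0.0


def test_compare_constant_offset():
    ref = {(f"s{i}", "PS"): 5.0 + i for i in range(5)}
    nmr = {k: v + 0.7 for k, v in ref.items()}
    rep = compare_to_reference(_long(nmr), _long(ref))
    assert rep.mean_absolute_deviation == pytest.approx(0.7, rel=1e-9)
    assert rep.per_compound.loc["PS", "r2_fit"] == pytest.approx(1.0)


def test_compare_statistics_match_brute_force():
    """Report statistics equal a direct recomputation from matched pairs."""
    rng = np.random.default_rng(42)
    ref = {(f"s{i}", c): float(rng.uniform(1, 10))
           for i in range(20) for c in ("PS", "PGOH")}
    nmr = {k: v + float(rng.normal(0, 0.5)) for k, v in ref.items()}
    rep = compare_to_reference(_long(nmr), _long(ref))
    n = np.array([nmr[k] for k in sorted(ref)])
    r = np.array([ref[k] for k in sorted(ref)])
    assert rep.mean_absolute_deviation == pytest.approx(np.mean(np.abs(n - r)), rel=1e-9)
    assert rep.mean_relative_deviation_pct == pytest.approx(
        100 * np.mean(np.abs(n - r) / r), rel=1e-9)
    for compound in ("PS", "PGOH"):
        mask = [k[1] == compound for k in sorted(ref)]
        x, y = r[mask], n[mask]
        expected = 1 - np.sum((y - x) ** 2) / np.sum((x - x.mean()) ** 2)
        assert rep.per_compound.loc[compound, "r2_identity"] == pytest.approx(expected, rel=1e-9)


def test_compare_reports_unmatched_and_small_n():
    nmr = _long({("s1", "PS"): 8.0, ("s2", "PS"): 8.1, ("s1", "XX"): 1.0})
    ref = _long({("s1", "PS"): 8.0, ("s2", "PS"): 8.0, ("s3", "PG"): 2.0})
    rep = compare_to_reference(nmr, ref)
    assert ("s1", "XX") in rep.unmatched_nmr
    assert ("s3", "PG") in rep.unmatched_ref
    assert np.isnan(rep.per_compound.loc["PS", "r2_identity"])  # n < 3
    assert any("fewer than 3" in n for n in rep.notes)


# -- pipeline runner ---------------------------------------------------------

def _write_config(tmp_path, samples):
    cfg = tmp_path / "run.yaml"
    lines = ["samples:"]
    for s in samples:
        lines.append(f"  - {s}")
    cfg.write_text("\n".join(lines) + "\n")
    return cfg


def test_run_pipeline_three_scenarios(tmp_path):
    cfg = _write_config(tmp_path, [
        "{name: a, scenario: propyl_selective, seed: 1}",
        "{name: b, scenario: oh_selective, seed: 2}",
        "{name: c, scenario: h2free_propenyl, seed: 3}",
    ])
    bundle = rq.run_pipeline(cfg, out_dir=tmp_path / "out")
    assert bundle["errors"] == {}
    df = bundle["results"]
    assert set(df["sample"]) == {"a", "b", "c"}
    assert (tmp_path / "out" / "provenance.json").exists()


def test_run_pipeline_deterministic(tmp_path):
    cfg = _write_config(tmp_path, ["{name: a, scenario: mixed_50_50, seed: 9}"])
    rq.run_pipeline(cfg, out_dir=tmp_path / "o1")
    rq.run_pipeline(cfg, out_dir=tmp_path / "o2")
    assert (tmp_path / "o1" / "results.csv").read_bytes() == \
        (tmp_path / "o2" / "results.csv").read_bytes()


def test_run_pipeline_continues_past_failures(tmp_path):
    cfg = _write_config(tmp_path, [
        "{name: good, scenario: propyl_selective, seed: 1}",
        "{name: bad, spectrum: /no/such/file.jdx}",
    ])
    bundle = rq.run_pipeline(cfg, out_dir=tmp_path / "out")
    assert "bad" in bundle["errors"]
    assert set(bundle["results"]["sample"]) == {"good"}
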
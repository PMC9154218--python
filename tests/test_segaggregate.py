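"""Segment aggregation, binned profiles and the bedMethyl/DSS writers."""

import math

import numpy as np
import pandas as pd
import pytest

import methkit as mk
from methkit.calls import CallState
from methkit.seqs import Reference
from methkit import segaggregate as sa


def _store_with(scores_at):
    """scores_at: list of (pos, score) on chr1, one read each."""
    store = mk.CallStore()
    cut = mk.CutoffConfig()
    store.add_calls(
        mk.ModCall(f"r{i}", "s1", "chr1", pos, "+", "m", s, mk.classify(s, cut))
        for i, (pos, s) in enumerate(scores_at)
    )
    return store


def test_segmeth_direct_counts():
    store = _store_with([(10, 5), (20, 5), (30, 5), (40, -5), (50, 1), (60, -1)])
    df = sa.segmeth(store, [mk.Segment("chr1", 0, 100)])
    row = df.iloc[0]
    assert (row.n_mod, row.n_unmod, row.n_ambig) == (3, 1, 2)
    assert row.meth_fraction == pytest.approx(0.75)
    assert row.n_reads == 6


def test_segmeth_only_ambig_fraction_is_na():
    store = _store_with([(10, 0.5), (20, -0.5)])
    df = sa.segmeth(store, [mk.Segment("chr1", 0, 100)])
    assert math.isnan(df.iloc[0].meth_fraction)
    assert df.iloc[0].n_ambig == 2


def test_segmeth_half_open_boundary():
    store = _store_with([(50, 5)])
    segs = [mk.Segment("chr1", 0, 50, name="a"), mk.Segment("chr1", 50, 100, name="b")]
    df = sa.segmeth(store, segs).set_index("name")
    assert df.loc["a", "n_mod"] == 0
    assert df.loc["b", "n_mod"] == 1


def test_segmeth_absent_chromosome_gives_zero_row():
    store = _store_with([(10, 5)])
    df = sa.segmeth(store, [mk.Segment("chrX", 0, 100)])
    row = df.iloc[0]
    assert (row.n_mod, row.n_unmod, row.n_ambig, row.n_reads) == (0, 0, 0, 0)


def test_segmeth_matches_bruteforce_loop(sim_bundle):
    """Random segments: aggregation equals a per-call python loop."""
    store = sim_bundle["store"]
    rng = np.random.default_rng(3)
    segs = []
    for _ in range(12):
        s = int(rng.integers(0, 7500))
        segs.append(mk.Segment("chr1", s, s + int(rng.integers(50, 800))))
    df = sa.segmeth(store, segs)
    calls = store.query("chr1")
    for seg, row in zip(segs, df.itertuples()):
        want = {"MOD": 0, "UNMOD": 0, "AMBIG": 0}
        reads = set()
        for c in calls:
            if seg.start <= c.ref_pos < seg.end:
                want[c.call.value] += 1
                reads.add(c.read_id)
        assert (row.n_mod, row.n_unmod, row.n_ambig) == (
            want["MOD"], want["UNMOD"], want["AMBIG"])
        assert row.n_reads == len(reads)


def test_segmeth_table_round_trip(tmp_path, sim_bundle):
    store = sim_bundle["store"]
    segs = [mk.Segment("chr1", 0, 4000, name="hi", group="g1"),
            mk.Segment("chr1", 4000, 8000, name="lo", group="g2")]
    df = sa.segmeth(store, segs)
    path = str(tmp_path / "seg.tsv")
    sa.write_segmeth_table(df, path)
    tidy = sa.read_segmeth_table(path)
    merged = tidy.merge(df, on=["name", "sample"], suffixes=("_r", ""))
    assert (merged["n_mod_r"].astype(int) == merged["n_mod"]).all()
    assert merged["meth_fraction_r"].values == pytest.approx(
        merged["meth_fraction"].values)


def test_bedmethyl_exact_line(tmp_path):
    store = _store_with([(104, 5), (104, 6), (104, 7), (104, -5)])
    # one read per call above shares position 104: 3 MOD, 1 UNMOD
    sites = sa.per_site_stats(store, "s1")
    path = str(tmp_path / "out.bedmethyl")
    n = sa.write_bedmethyl(sites, path)
    assert n == 1
    line = open(path).read().rstrip("\n")
    assert line == "chr1\t104\t105\tm\t4\t+\t104\t105\t0,0,0\t4\t75"


def test_bedmethyl_skips_unclassified_and_sorts(tmp_path):
    rng = np.random.default_rng(4)
    entries = [(int(p), float(s)) for p, s in
               zip(rng.integers(0, 5000, 300), rng.normal(0, 4, 300))]
    entries.append((9999, 0.1))  # lone AMBIG site -> no line
    store = _store_with(entries)
    sites = sa.per_site_stats(store, "s1")
    path = str(tmp_path / "out.bedmethyl")
    sa.write_bedmethyl(sites, path)
    df = sa.read_bedmethyl(path)
    assert (df["start"].diff().dropna() >= 0).all()
    assert 9999 not in set(df["start"])
    assert (df["coverage"] >= 1).all()


def test_bedmethyl_round_trip_recovers_counts(tmp_path, sim_bundle):
    store = sim_bundle["store"]
    sites = sa.per_site_stats(store, "s1")
    path = str(tmp_path / "rt.bedmethyl")
    sa.write_bedmethyl(sites, path)
    back = sa.read_bedmethyl(path)
    covered = sites[sites["coverage"] > 0].reset_index(drop=True)
    assert len(back) == len(covered)
    assert (back["start"].to_numpy() == covered["ref_pos"].to_numpy()).all()
    assert (back["coverage"].to_numpy() == covered["coverage"].to_numpy()).all()
    want_pct = (100 * covered["meth_fraction"]).round().astype(int).to_numpy()
    assert (back["percent"].to_numpy() == want_pct).all()


def test_dss_table_format(tmp_path):
    store = _store_with([(104, 5), (104, 6), (104, 7), (104, -5)])
    sites = sa.per_site_stats(store, "s1")
    path = str(tmp_path / "dss.tsv")
    sa.write_dss_table(sites, path)
    lines = open(path).read().splitlines()
    assert lines[0] == "chr\tpos\tN\tX"
    assert lines[1] == "chr1\t105\t4\t3"


def test_dss_x_bounded_by_n(tmp_path, sim_bundle):
    sites = sa.per_site_stats(sim_bundle["store"], "s1")
    path = str(tmp_path / "dss.tsv")
    sa.write_dss_table(sites, path)
    df = pd.read_csv(path, sep="\t")
    assert (df["X"] <= df["N"]).all()
    assert (df["N"] >= 1).all()


def test_dss_empty_store_header_only(tmp_path):
    store = mk.CallStore()
    sites = sa.per_site_stats(store, "s1")
    path = str(tmp_path / "dss.tsv")
    sa.write_dss_table(sites, path)
    assert open(path).read() == "chr\tpos\tN\tX\n"


# ---------------------------------------------------------------------------
# binned whole-genome profiles
# ---------------------------------------------------------------------------


def test_binned_bin_count_is_ceiling():
    store = _store_with([(10, 5)])
    ref = Reference({"chr1": "ACGT" * 250})  # 1000 bp
    bdf = sa.wgmeth_binned(store, "s1", 500, ref)
    assert len(bdf) == 2
    bdf2 = sa.wgmeth_binned(store, "s1", 300, ref)
    assert len(bdf2) == 4
    assert bool(bdf2.iloc[-1].partial) is True
    with pytest.raises(ValueError):
        sa.wgmeth_binned(store, "s1", 0, ref)


def test_binned_fraction_and_motif_count():
    seq = "TTCGTT" * 10  # 10 CpGs in 60 bp
    calls = [(i * 6 + 2, 5.0) for i in range(8)] + [(50, -5.0), (56, -5.0)]
    store = _store_with(calls)
    bdf = sa.wgmeth_binned(store, "s1", 60, Reference({"chr1": seq}))
    row = bdf.iloc[0]
    assert row.n_motif_sites == 10
    assert row.meth_fraction == pytest.approx(0.8)


def test_binned_masking_and_conservation(sim_bundle):
    store, ref = sim_bundle["store"], sim_bundle["ref"]
    bdf = sa.wgmeth_binned(store, "s1", 250, ref)
    # no-motif bins are masked with no fraction
    masked = bdf[bdf["masked"]]
    assert masked["meth_fraction"].isna().all()
    # per-bin call counts sum to the chromosome total
    total = store.n_calls("s1")
    assert int((bdf.n_mod + bdf.n_unmod + bdf.n_ambig).sum()) == total
    # bins tile without overlap
    assert (bdf["start"].to_numpy()[1:] == bdf["end"].to_numpy()[:-1]).all()


def test_parameter_recovery_single_run(sim_bundle):
    """Estimated fraction within 4 binomial SE of truth on both intervals."""
    from conftest import TRUE_P

    store = sim_bundle["store"]
    segs = [mk.Segment("chr1", s, e) for s, e, _ in TRUE_P]
    df = sa.segmeth(store, segs)
    for (s, e, p), row in zip(TRUE_P, df.itertuples()):
        m = row.n_mod + row.n_unmod
        se = math.sqrt(p * (1 - p) / m)
        assert abs(row.meth_fraction - p) <= 4 * se
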
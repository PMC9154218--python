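"""BAM MM/ML import (with brute-force decoding oracle) and tabular dialects."""

import array
import math

import numpy as np
import pysam
import pytest

import methkit as mk
from methkit.calls import CallState
from conftest import make_random_tagged_read, mm_decode_oracle, write_bam

HEADER = {"HD": {"VN": "1.6", "SO": "coordinate"},
          "SQ": [{"SN": "chr1", "LN": 2000}]}


def _read(name="r1", seq="ACGTCGTTCG", flag=0, start=100, cigar="10M",
          mm="C+m,1,0;", ml=(230, 26), extra_tags=()):
    a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(HEADER))
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = cigar
    tags = [("MM", mm)]
    if ml is not None:
        tags.append(("ML", array.array("B", list(ml))))
    tags.extend(extra_tags)
    a.set_tags(tags)
    return a


def test_hand_traced_mm_example(tmp_path):
    """ACGTCGTTCG with MM C+m,1,0 / ML 230,26 yields calls at 104 and 108."""
    bam = str(tmp_path / "t.bam")
    write_bam(bam, [_read()], HEADER)
    store = mk.import_bam_modcalls(bam, "s1", motif=None)
    calls = {c.ref_pos: c for c in store.query("chr1")}
    assert set(calls) == {104, 108}
    assert calls[104].score == pytest.approx(math.log(230.5 / 25.5), abs=1e-9)
    assert calls[104].score == pytest.approx(2.2016, abs=5e-4)
    assert calls[108].score == pytest.approx(-2.1586, abs=5e-4)
    assert calls[104].call is CallState.MOD
    assert calls[108].call is CallState.UNMOD


def test_empty_mm_list_emits_nothing(tmp_path):
    bam = str(tmp_path / "t.bam")
    write_bam(bam, [_read(mm="C+m;", ml=())], HEADER)
    store = mk.import_bam_modcalls(bam, "s1")
    assert store.n_calls() == 0


def test_call_in_insertion_dropped(tmp_path):
    # 5M2I5M: query CC inserted after 5 aligned bases; a modified C inside
    # the insertion has no reference coordinate and is dropped.
    seq = "AAAAA" + "CC" + "TTTCG"
    # C occurrences in read order: 5, 6, 10 -> list all three as modified
    bam = str(tmp_path / "t.bam")
    write_bam(bam, [_read(seq=seq, cigar="5M2I5M", mm="C+m,0,0,0;",
                          ml=(200, 210, 220))], HEADER)
    store = mk.import_bam_modcalls(bam, "s1", motif=None)
    calls = store.query("chr1")
    assert [c.ref_pos for c in calls] == [108]  # only the aligned C survives
    assert calls[0].score == pytest.approx(math.log(220.5 / 35.5), rel=1e-9)


def test_mm_ml_length_mismatch_skips_read(tmp_path):
    bad = _read(name="bad", mm="C+m,1,0;", ml=(230,))
    good = _read(name="good")
    bam = str(tmp_path / "t.bam")
    write_bam(bam, [bad, good], HEADER)
    store = mk.import_bam_modcalls(bam, "s1", motif=None)
    assert {c.read_id for c in store.query("chr1")} == {"good"}
    assert store.import_reports[-1].warnings  # mismatch logged


def test_missing_index_is_an_error(tmp_path):
    bam = str(tmp_path / "t.bam")
    with pysam.AlignmentFile(bam, "wb", header=HEADER) as fh:
        fh.write(_read())
    with pytest.raises(Exception):
        mk.import_bam_modcalls(bam, "s1")


def test_other_mod_code_subtag_ignored(tmp_path):
    bam = str(tmp_path / "t.bam")
    write_bam(bam, [_read(mm="A+a,0;", ml=(250,))], HEADER)
    store = mk.import_bam_modcalls(bam, "s1", mod_code="m", motif=None)
    assert store.n_calls() == 0


def test_hp_ps_tags_populate_phase_fields(tmp_path):
    bam = str(tmp_path / "t.bam")
    write_bam(bam, [_read(extra_tags=[("HP", 2), ("PS", 77)])], HEADER)
    store = mk.import_bam_modcalls(bam, "s1", motif=None)
    c = store.query("chr1")[0]
    assert c.haplotype == 2
    assert c.phase_set == "77"


def test_reverse_strand_cpg_collapses_to_plus_c(tmp_path):
    # SEQ spans ref 200..209 = ACGTCGTTCG; original read = revcomp(SEQ).
    # MM C+m,0,1 marks orig idx 0 and 7 -> SEQ idx 9 and 2 -> ref 209, 202.
    # ref 209 is not part of a CG in SEQ; use the CG at 204/205: the
    # minus-strand C sits at ref 205 (SEQ idx 5 G); orig idx = 4.
    rev = _read(name="rev", flag=16, start=200, mm="C+m,1;", ml=(240,))
    # orig = CGAACGACGT; C occurrences at 0,4,7; skip 1 -> orig idx 4 ->
    # SEQ idx 5 -> ref 205 (the CpG G) -> collapsed to 204 on '+'
    bam = str(tmp_path / "t.bam")
    write_bam(bam, [rev], HEADER)
    store = mk.import_bam_modcalls(bam, "s1", motif="CG")
    c = store.query("chr1")[0]
    assert (c.ref_pos, c.strand) == (204, "+")
    # without collapsing the call stays on the minus-strand base
    store2 = mk.import_bam_modcalls(bam, "s2", motif=None)
    c2 = store2.query("chr1", sample="s2")[0]
    assert (c2.ref_pos, c2.strand) == (205, "-")


def test_mm_decoding_matches_bruteforce_oracle(tmp_path):
    """Random reads with random CIGARs decode to the oracle's positions."""
    rng = np.random.default_rng(99)
    header = pysam.AlignmentHeader.from_dict(HEADER)
    reads = [make_random_tagged_read(rng, header, f"r{i}") for i in range(200)]
    bam = str(tmp_path / "rand.bam")
    write_bam(bam, reads, HEADER)
    store = mk.import_bam_modcalls(bam, "s1", motif=None)
    got = {}
    for c in store.query("chr1"):
        byte = round(256 * mk.llr_to_probability(c.score) - 0.5)
        got.setdefault(c.read_id, []).append((c.ref_pos, int(byte)))
    for r in reads:
        expected = mm_decode_oracle(
            r.query_sequence, r.is_reverse, r.cigartuples, r.reference_start,
            r.get_tag("MM"), list(r.get_tag("ML")) if r.has_tag("ML") else [],
        )
        assert sorted(got.get(r.query_name, [])) == expected, r.query_name


# ---------------------------------------------------------------------------
# tabular dialects
# ---------------------------------------------------------------------------


def test_custom_table_probabilities_to_llr(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(
        "r1\tchr1\t100\t0.99\nr2\tchr1\t200\t0.5\nr3\tchr1\t300\t0.01\n"
    )
    spec = mk.ColumnSpec(read_id=0, chrom=1, pos=2, score=3)
    store = mk.import_tabular(str(path), "custom", "s1", column_spec=spec)
    by_pos = {c.ref_pos: c.score for c in store.query("chr1")}
    assert by_pos[100] == pytest.approx(math.log(99), rel=1e-9)
    assert by_pos[200] == pytest.approx(0.0, abs=1e-12)
    assert by_pos[300] == pytest.approx(-math.log(99), rel=1e-9)


def test_nanopolish_group_expansion(tmp_path):
    seq = "AATTCGAAAACGTT"  # CGs at offsets 4 and 10 -> positions 1000, 1006
    path = tmp_path / "np.tsv"
    path.write_text(
        "chromosome\tstrand\tstart\tend\tread_name\tlog_lik_ratio\t"
        "log_lik_methylated\tlog_lik_unmethylated\tnum_calling_strands\t"
        "num_motifs\tsequence\n"
        f"chr1\t+\t1000\t1006\trA\t3.1\t3.1\t0.0\t1\t2\t{seq}\n"
    )
    store = mk.import_tabular(str(path), "nanopolish", "s1")
    calls = store.query("chr1")
    assert [(c.ref_pos, c.score) for c in calls] == [(1000, 3.1), (1006, 3.1)]


def test_megalodon_llr_is_logprob_difference(tmp_path):
    path = tmp_path / "mega.tsv"
    path.write_text(
        "read_id\tchrm\tstrand\tpos\tmod_log_prob\tcan_log_prob\tmod_base\n"
        "r1\tchr1\t+\t50\t-0.10536\t-2.30259\tm\n"
    )
    store = mk.import_tabular(str(path), "megalodon", "s1")
    c = store.query("chr1")[0]
    assert c.score == pytest.approx(-0.10536 + 2.30259, rel=1e-6)


def test_unparseable_rows_counted_not_fatal(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("r1\tchr1\t100\t0.9\nr2\tchr1\tnot_a_pos\t0.5\n")
    spec = mk.ColumnSpec(read_id=0, chrom=1, pos=2, score=3)
    store = mk.import_tabular(str(path), "custom", "s1", column_spec=spec)
    rep = store.import_reports[-1]
    assert (rep.n_accepted, rep.n_skipped) == (1, 1)


def test_empty_table_is_an_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    spec = mk.ColumnSpec(read_id=0, chrom=1, pos=2, score=3)
    with pytest.raises(ValueError, match="zero accepted rows"):
        mk.import_tabular(str(path), "custom", "s1", column_spec=spec)


def test_simulated_tabular_round_trip(sim_bundle, tmp_path):
    """Megalodon/nanopolish/custom writers re-import to consistent calls."""
    from methkit import simulate as sim

    rt = sim_bundle["reads"].read_truth
    chrom = sim_bundle["simref"].chrom
    ref_seq = sim_bundle["simref"].sequence

    mega = tmp_path / "mega.tsv"
    sim.write_megalodon_table(rt, chrom, str(mega))
    store = mk.import_tabular(str(mega), "megalodon", "m1")
    assert store.n_calls() == len(rt)

    cust = tmp_path / "cust.tsv"
    sim.write_custom_table(rt, chrom, str(cust))
    spec = mk.ColumnSpec(read_id=0, chrom=1, pos=2, score=3)
    store2 = mk.import_tabular(str(cust), "custom", "c1", column_spec=spec)
    assert store2.n_calls() == len(rt)

    np_path = tmp_path / "np.tsv"
    sim.write_nanopolish_table(rt, chrom, ref_seq, str(np_path))
    store3 = mk.import_tabular(str(np_path), "nanopolish", "n1")
    # group expansion emits one call per (read, site): same count as truth
    assert store3.n_calls() == len(rt)
    # emitted positions equal the truth site set
    got = {(c.read_id, c.ref_pos) for c in store3.query(chrom)}
    want = {(r.read_id, int(r.pos)) for r in rt.itertuples()}
    assert got == want
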
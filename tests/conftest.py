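"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
MM/ML decoding is re-derived by walking read and reference base-by-base,
and consensus alignment by a dense affine-gap dynamic program.
"""

from __future__ import annotations

import array
import os

import numpy as np
import pysam
import pytest

import methkit as mk
from methkit.seqs import Reference, revcomp

# ---------------------------------------------------------------------------
# brute-force MM/ML decoder (independent of pysam.modified_bases)
# ---------------------------------------------------------------------------

_CONSUME_Q = {0: True, 1: True, 4: True, 7: True, 8: True}
_CONSUME_R = {0: True, 2: True, 3: True, 7: True, 8: True}


def mm_decode_oracle(seq, is_reverse, cigartuples, ref_start, mm, ml,
                     canonical="C", mod_code="m"):
    """Decode MM/ML by hand: returns sorted [(ref_pos, byte), ...].

    Walks the original-orientation read to place skip counts, flips to SEQ
    orientation for reverse reads, then walks the CIGAR base-by-base to
    lift query positions to the reference (M/=/X columns only).
    """
    # 1. parse the MM sub-tag for this canonical base / modification
    skips = None
    for sub in mm.strip(";").split(";"):
        if not sub:
            continue
        head, _, body = sub.partition(",")
        base, strand_ch = head[0], head[1]
        code = head[2:].rstrip("?.")
        if base == canonical and strand_ch == "+" and code == mod_code:
            skips = [int(x) for x in body.split(",")] if body else []
            break
    if skips is None:
        return []

    # 2. original-orientation read and its canonical-base occurrences
    orig = revcomp(seq) if is_reverse else seq
    canon_idx = [i for i, b in enumerate(orig) if b == canonical]
    orig_positions = []
    ptr = 0
    for s in skips:
        ptr += s
        if ptr >= len(canon_idx):
            return []  # malformed: more skips than canonical bases
        orig_positions.append(canon_idx[ptr])
        ptr += 1

    # 3. to SEQ orientation
    L = len(seq)
    seq_positions = [L - 1 - p if is_reverse else p for p in orig_positions]

    # 4. lift through the CIGAR, base by base
    q2r = {}
    q, r = 0, ref_start
    for op, n in cigartuples:
        for _ in range(n):
            cq = _CONSUME_Q.get(op, False)
            cr = _CONSUME_R.get(op, False)
            if cq and cr:
                q2r[q] = r
            if cq:
                q += 1
            if cr:
                r += 1

    out = []
    for sp, byte in zip(seq_positions, ml):
        rp = q2r.get(sp)
        if rp is not None:
            out.append((rp, byte))
    return sorted(out)


def make_random_tagged_read(rng, header, name, max_len=50, max_mods=8,
                            canonical="C", mod_code="m"):
    """A random aligned read with random CIGAR and MM/ML tags.

    CIGAR ops are drawn from {M, I, D, S} with soft clips only at the
    ends; a random subset of canonical bases (in original orientation)
    is listed as modified.
    """
    length = int(rng.integers(10, max_len + 1))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    is_rev = bool(rng.random() < 0.5)

    # random CIGAR consuming exactly `length` query bases; the aligned part
    # has the shape M (gap M)* so it legally starts and ends on a match run
    lead_clip = int(rng.integers(0, 4)) if rng.random() < 0.3 else 0
    tail_clip = int(rng.integers(0, 4)) if rng.random() < 0.3 else 0
    lead_clip = min(lead_clip, length - 1)
    tail_clip = min(tail_clip, length - 1 - lead_clip)
    q = length - lead_clip - tail_clip
    ops = []
    run = int(rng.integers(1, q + 1))
    ops.append((0, run))
    q -= run
    while q > 0:
        if rng.random() < 0.4:
            ops.append((2, int(rng.integers(1, 6))))  # deletion
        elif q > 1:
            ins = int(rng.integers(1, q))  # insertion, keep >=1 for final M
            ops.append((1, ins))
            q -= ins
        run = int(rng.integers(1, q + 1))
        ops.append((0, run))
        q -= run
    merged = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    ops = ([(4, lead_clip)] if lead_clip else []) + merged + \
        ([(4, tail_clip)] if tail_clip else [])
    assert sum(n for op, n in ops if _CONSUME_Q.get(op, False)) == length

    orig = revcomp(seq) if is_rev else seq
    canon_idx = [i for i, b in enumerate(orig) if b == canonical]
    k = int(rng.integers(0, min(max_mods, len(canon_idx)) + 1))
    chosen = sorted(rng.choice(len(canon_idx), size=k, replace=False)) if k else []
    skips = []
    prev = -1
    for c in chosen:
        skips.append(int(c - prev - 1))
        prev = c
    mm = f"{canonical}+{mod_code}," + ",".join(map(str, skips)) + ";" if skips \
        else f"{canonical}+{mod_code};"
    ml = [int(rng.integers(0, 256)) for _ in skips]

    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 16 if is_rev else 0
    a.reference_id = 0
    a.reference_start = int(rng.integers(0, 500))
    a.mapping_quality = 60
    a.cigartuples = ops
    a.set_tags([("MM", mm), ("ML", array.array("B", ml))])
    return a


def write_bam(path, records, header_dict):
    records = sorted(records, key=lambda r: (r.reference_start, r.query_name))
    with pysam.AlignmentFile(path, "wb", header=header_dict) as bam:
        for r in records:
            bam.write(r)
    pysam.index(path)


# ---------------------------------------------------------------------------
# affine-gap alignment oracle (Gotoh, element-ends free)
# ---------------------------------------------------------------------------

NEG = -1e18


def gotoh_oracle(cons, elem, match=2.0, mismatch=-3.0, gap_open=5.0,
                 gap_extend=2.0):
    """Optimal global score, consensus-global / element-ends-free.

    A gap run of length L costs gap_open + L*gap_extend except runs of
    consensus overhang at either end (gaps in the element row), which are
    free.  Returns the optimal score only; mappings are validated
    separately by re-scoring.
    """
    n, m = len(cons), len(elem)
    first = gap_open + gap_extend
    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)  # gap in element (consensus consumed)
    I = np.full((n + 1, m + 1), NEG)  # gap in consensus (element consumed)
    M[0, 0] = 0.0
    D[:, 0] = 0.0  # leading consensus overhang is free
    for j in range(1, m + 1):
        I[0, j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if cons[i - 1] == elem[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1]) + s
            D[i, j] = max(M[i - 1, j] - first, D[i - 1, j] - gap_extend,
                          I[i - 1, j] - first)
            I[i, j] = max(M[i, j - 1] - first, I[i, j - 1] - gap_extend,
                          D[i, j - 1] - first)
    # trailing consensus overhang free: best over all i at j = m
    return float(max(M[:, m].max(), D[:, m].max(), I[:, m].max()))


def score_mapping(cons, elem, mapping, match=2.0, mismatch=-3.0,
                  gap_open=5.0, gap_extend=2.0):
    """Score of the (unique up to gap interleaving) alignment a mapping
    implies, under the same scheme as :func:`gotoh_oracle`."""
    if not mapping:
        return -(gap_open + gap_extend * len(elem)) if elem else 0.0
    pairs = sorted(mapping.items())  # (elem_idx, cons_idx)
    score = 0.0

    def gap_cost(L):
        return gap_open + gap_extend * L if L > 0 else 0.0

    e_prev, c_prev = pairs[0]
    # leading: element overhang penalized, consensus overhang free
    score -= gap_cost(e_prev)
    score += match if cons[c_prev] == elem[e_prev] else mismatch
    for e, c in pairs[1:]:
        assert e > e_prev and c > c_prev, "mapping not strictly monotone"
        score -= gap_cost(e - e_prev - 1)   # insertion run
        score -= gap_cost(c - c_prev - 1)   # deletion run
        score += match if cons[c] == elem[e] else mismatch
        e_prev, c_prev = e, c
    score -= gap_cost(len(elem) - 1 - e_prev)  # trailing element overhang
    return score


# ---------------------------------------------------------------------------
# simulated datasets
# ---------------------------------------------------------------------------

TRUE_P = ((0, 4000, 0.9), (4000, 8000, 0.1))


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Reference + reads at two known methylation levels, imported."""
    cfg = mk.SimConfig(seed=11, ref_length=8000, depth=10,
                       prob_intervals=TRUE_P,
                       repeat=mk.RepeatSpec(consensus_length=300, n_copies=3))
    simref = mk.simulate_reference(cfg)
    d = tmp_path_factory.mktemp("sim")
    reads = mk.simulate_reads(cfg, simref, str(d))
    store = mk.import_bam_modcalls(reads.bam_path, "s1")
    ref = Reference({simref.chrom: simref.sequence})
    return {"cfg": cfg, "simref": simref, "reads": reads, "store": store,
            "ref": ref, "dir": d}


@pytest.fixture(scope="session")
def phased_bundle(tmp_path_factory):
    """Phased reads: hap1 methylated (0.9), hap2 unmethylated (0.1)."""
    cfg = mk.SimConfig(seed=23, ref_length=6000, depth=14, phased=True,
                       default_p=0.5,
                       hap_probs={1: [(0, 6000, 0.9)], 2: [(0, 6000, 0.1)]})
    simref = mk.simulate_reference(cfg)
    d = tmp_path_factory.mktemp("phased")
    reads = mk.simulate_reads(cfg, simref, str(d))
    store = mk.import_bam_modcalls(reads.bam_path, "s1")
    ref = Reference({simref.chrom: simref.sequence})
    return {"cfg": cfg, "simref": simref, "reads": reads, "store": store,
            "ref": ref}


@pytest.fixture()
def manual_store():
    """Tiny hand-built store for exact-count assertions."""
    store = mk.CallStore()
    cut = mk.CutoffConfig(-2, 2)
    rows = []
    for i, (pos, score) in enumerate([(10, 5.0), (20, 5.0), (30, 4.0),
                                      (40, -5.0), (50, 1.0), (60, -1.0)]):
        rows.append(mk.ModCall(f"r{i}", "s1", "chr1", pos, "+", "m",
                               score, mk.classify(score, cut)))
    store.add_calls(rows)
    return store
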
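"""Synthetic references and MM/ML-tagged reads with known methylation truth.

The generator emulates a small nanopore modified-base experiment: a random
reference (optionally with planted, mutated/truncated copies of a repeat
consensus), per-site true modification probabilities (optionally
haplotype-specific), and aligned reads whose MM/ML tags encode scores drawn
from a two-component Gaussian score model

    LLR | modified   ~ N(+4, 1.5)
    LLR | unmodified ~ N(-4, 1.5)

transformed to ML probability bytes through the logistic, which reproduces
the bimodal per-read score distribution typical of real callers.  Each
read/site modification state is an independent Bernoulli draw from the true
site probability, so downstream estimates can be checked against binomial
error bounds.  Everything is driven by a single integer seed and output is
byte-reproducible (reads are coordinate-sorted in memory before writing, so
the BAM contains no run-specific program lines).
"""

from __future__ import annotations

import array
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .seqs import motif_positions, revcomp
from .segaggregate import Segment

BASES = np.array(list("ACGT"))


@dataclass
class ScoreModel:
    """State-conditional Gaussian model of per-call log-probability ratios."""

    mod_mean: float = 4.0
    unmod_mean: float = -4.0
    sd: float = 1.5


@dataclass
class RepeatSpec:
    """A planted repeat family: consensus plus mutated/truncated copies."""

    consensus_length: int = 600
    n_copies: int = 5
    mutation_rate: float = 0.02
    truncation_prob: float = 0.0
    max_truncation_frac: float = 0.5
    minus_strand_prob: float = 0.0


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment; ``seed`` is mandatory."""

    seed: int
    ref_length: int = 20_000
    chrom: str = "chr1"
    gc: float = 0.5
    motif: str = "CG"
    default_p: float = 0.8
    prob_intervals: Sequence[Tuple[int, int, float]] = ()
    hap_probs: Optional[Dict[int, Sequence[Tuple[int, int, float]]]] = None
    phased: bool = False
    read_length_mean: int = 1000
    read_length_sd: float = 200.0
    min_read_length: int = 100
    depth: int = 15
    score_model: ScoreModel = field(default_factory=ScoreModel)
    frac_reverse: float = 0.5
    indel_rate: float = 0.0
    repeat: Optional[RepeatSpec] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for s, e, p in self.prob_intervals:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    def site_probability(self, pos: int, haplotype: Optional[int] = None) -> float:
        """True modification probability at a site (haplotype-aware)."""
        if haplotype is not None and self.hap_probs:
            for s, e, p in self.hap_probs.get(haplotype, ()):
                if s <= pos < e:
                    return p
        for s, e, p in self.prob_intervals:
            if s <= pos < e:
                return p
        return self.default_p


@dataclass
class SimReference:
    chrom: str
    sequence: str
    repeat_elements: List[Segment]
    consensus: Optional[str]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=probs))


def simulate_reference(config: SimConfig) -> SimReference:
    """Random reference sequence, optionally with planted repeat copies.

    Copies are placed at evenly spaced, non-overlapping offsets; each copy
    is independently substituted at ``mutation_rate``, optionally 5'
    truncated, and optionally inserted on the minus strand (i.e. the
    reverse complement is written into the reference).
    """
    rng = np.random.default_rng(config.seed)
    seq = list(_random_seq(rng, config.ref_length, config.gc))
    elements: List[Segment] = []
    consensus = None
    if config.repeat is not None:
        rs = config.repeat
        consensus = _random_seq(rng, rs.consensus_length, config.gc)
        spacing = config.ref_length // (rs.n_copies + 1)
        if spacing <= rs.consensus_length:
            raise ValueError("reference too short for requested repeat copies")
        for i in range(rs.n_copies):
            copy = np.array(list(consensus))
            mut = rng.random(copy.size) < rs.mutation_rate
            copy[mut] = rng.choice(BASES, size=int(mut.sum()))
            copy_seq = "".join(copy)
            if rng.random() < rs.truncation_prob:
                cut = int(rng.integers(1, int(rs.max_truncation_frac * len(copy_seq)) + 1))
                copy_seq = copy_seq[cut:]  # 5' truncation
            strand = "-" if rng.random() < rs.minus_strand_prob else "+"
            placed = copy_seq if strand == "+" else revcomp(copy_seq)
            start = (i + 1) * spacing
            end = start + len(placed)
            seq[start:end] = list(placed)
            elements.append(
                Segment(config.chrom, start, end, name=f"rep{i}", strand=strand,
                        group="repeat")
            )
    return SimReference(
        chrom=config.chrom, sequence="".join(seq),
        repeat_elements=elements, consensus=consensus,
    )


def write_fasta(path: str, records: Dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class SimReads:
    bam_path: str
    truth_sites: pd.DataFrame   # pos, haplotype, true_p
    read_truth: pd.DataFrame    # read_id, pos, haplotype, state, llr, byte, strand
    n_reads: int


def _llr_to_byte(llr: float) -> int:
    p = 1.0 / (1.0 + math.exp(-llr))
    return int(min(255, max(0, math.floor(p * 256.0))))


def _mm_ml_tags(seq: str, modified: Dict[int, int], canonical: str = "C",
                mod_code: str = "m") -> Tuple[str, "array.array"]:
    """Build MM/ML tags: ``modified`` maps read positions (in the given
    orientation) to ML bytes; skip counts run over canonical-base
    occurrences in read order."""
    skips = []
    bytes_ = []
    n_skipped = 0
    mod_pos = set(modified)
    for i, b in enumerate(seq):
        if b != canonical:
            continue
        if i in mod_pos:
            skips.append(str(n_skipped))
            bytes_.append(modified[i])
            n_skipped = 0
        else:
            n_skipped += 1
    mm = f"{canonical}+{mod_code}," + ",".join(skips) + ";" if skips else f"{canonical}+{mod_code};"
    return mm, array.array("B", bytes_)


def simulate_reads(
    config: SimConfig,
    simref: SimReference,
    out_dir: str,
    sample: str = "sim",
) -> SimReads:
    """Simulate MM/ML-tagged aligned reads over a simulated reference.

    Writes ``<out_dir>/<sample>.bam`` (coordinate-sorted, indexed) plus the
    truth tables.  Reverse-strand reads carry MM tags constructed over the
    reverse complement, exercising the decoder's orientation handling; with
    ``indel_rate > 0`` forward reads additionally acquire insertions and
    deletions (and CIGARs to match).
    """
    rng = np.random.default_rng(config.seed + 1)
    ref_seq = simref.sequence
    ref_len = len(ref_seq)
    chrom = simref.chrom
    sites = motif_positions(ref_seq, config.motif, 0)
    n_reads = max(1, int(math.ceil(config.depth * ref_len / config.read_length_mean)))
    if n_reads == 0:
        raise ValueError("configuration yields zero reads")

    truth_site_rows = []
    haps = [None] if not config.phased else [1, 2]
    for pos in sites:
        for h in haps:
            truth_site_rows.append(
                {"pos": int(pos), "haplotype": h,
                 "true_p": config.site_probability(int(pos), h)}
            )
    truth_sites = pd.DataFrame(truth_site_rows)

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": ref_len}]}
    os.makedirs(out_dir, exist_ok=True)
    bam_path = os.path.join(out_dir, f"{sample}.bam")

    records = []
    read_truth_rows = []
    sm = config.score_model
    for ridx in range(n_reads):
        length = int(max(config.min_read_length,
                         rng.normal(config.read_length_mean, config.read_length_sd)))
        length = min(length, ref_len)
        start = int(rng.integers(0, ref_len - length + 1))
        is_rev = rng.random() < config.frac_reverse
        hap = int(rng.integers(1, 3)) if config.phased else None
        read_id = f"read{ridx:06d}"

        # alignment construction: forward reads may carry indels
        if not is_rev and config.indel_rate > 0:
            qseq, cig_ops, ref2q = _walk_with_indels(
                rng, ref_seq, start, length, config.indel_rate
            )
            end = start + sum(n for op, n in cig_ops if op in (0, 2))
        else:
            qseq = ref_seq[start : start + length]
            cig_ops = [(0, length)]
            ref2q = {start + i: i for i in range(length)}
            end = start + length

        # per-site draws for motif sites covered by the alignment
        modified_fwd: Dict[int, int] = {}
        for pos in sites[(sites >= start) & (sites < end)]:
            pos = int(pos)
            q = ref2q.get(pos)
            qg = ref2q.get(pos + 1)  # CpG G (needed for reverse reads)
            if is_rev and qg is None:
                continue
            if not is_rev and q is None:
                continue
            p_true = config.site_probability(pos, hap)
            state = int(rng.random() < p_true)
            mean = sm.mod_mean if state else sm.unmod_mean
            llr = float(rng.normal(mean, sm.sd)) if sm.sd > 0 else mean
            byte = _llr_to_byte(llr)
            qpos = q if not is_rev else qg
            modified_fwd[qpos] = byte
            read_truth_rows.append(
                {"read_id": read_id, "pos": pos, "haplotype": hap,
                 "state": state, "llr": llr, "byte": byte,
                 "strand": "-" if is_rev else "+"}
            )

        if is_rev:
            orig = revcomp(qseq)
            L = len(qseq)
            modified = {L - 1 - q: b for q, b in modified_fwd.items()}
        else:
            orig, modified = qseq, modified_fwd

        mm, ml = _mm_ml_tags(orig, modified)
        a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
        a.query_name = read_id
        a.query_sequence = qseq
        a.flag = 16 if is_rev else 0
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigartuples = cig_ops
        tags = [("MM", mm), ("ML", ml)]
        if config.phased and hap is not None:
            tags += [("HP", hap), ("PS", 1)]
        a.set_tags(tags)
        records.append(a)

    records.sort(key=lambda r: (r.reference_start, r.query_name))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for r in records:
            bam.write(r)
    pysam.index(bam_path)

    return SimReads(
        bam_path=bam_path, truth_sites=truth_sites,
        read_truth=pd.DataFrame(read_truth_rows), n_reads=n_reads,
    )


def _walk_with_indels(rng, ref_seq, start, length, indel_rate):
    """Walk the reference emitting M/I/D ops; returns (query, CIGAR, ref→query)."""
    q = []
    ops = []  # (op, len) with pysam codes 0=M, 1=I, 2=D
    ref2q = {}
    rpos = start
    end = min(start + length, len(ref_seq))

    def push(op, n=1):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    while rpos < end:
        u = rng.random()
        if u < indel_rate / 2 and q:  # insertion
            q.append(str(rng.choice(BASES)))
            push(1)
        elif u < indel_rate and (end - rpos) > 1 and q:  # deletion
            push(2)
            rpos += 1
        else:
            ref2q[rpos] = len(q)
            q.append(ref_seq[rpos])
            push(0)
            rpos += 1
    return "".join(q), ops, ref2q


# ---------------------------------------------------------------------------
# tabular caller-output emulation (from the per-read truth table)
# ---------------------------------------------------------------------------


def write_megalodon_table(read_truth: pd.DataFrame, chrom: str, path: str) -> None:
    """Per-read megalodon-style text: LLR split into mod/can log-probs."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrm\tstrand\tpos\tmod_log_prob\tcan_log_prob\tmod_base\n")
        for r in read_truth.itertuples():
            p = 1.0 / (1.0 + math.exp(-r.llr))
            p = min(max(p, 1e-12), 1 - 1e-12)
            fh.write(
                f"{r.read_id}\t{chrom}\t+\t{int(r.pos)}\t"
                f"{math.log(p):.6f}\t{math.log(1 - p):.6f}\tm\n"
            )


def write_nanopolish_table(
    read_truth: pd.DataFrame, chrom: str, ref_seq: str, path: str,
    group_distance: int = 10, context: int = 5,
) -> None:
    """Nanopolish-style methylation calls with multi-CpG grouping.

    Within a read, motif sites closer than ``group_distance`` are merged
    into one row whose log_lik_ratio is the mean of the member scores and
    whose sequence field carries the reference context, exactly as the
    importer's group-expansion rule expects.
    """
    cols = "chromosome\tstrand\tstart\tend\tread_name\tlog_lik_ratio\tlog_lik_methylated\tlog_lik_unmethylated\tnum_calling_strands\tnum_motifs\tsequence\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for read_id, sub in read_truth.groupby("read_id", sort=True):
            sub = sub.sort_values("pos")
            group: List[Tuple[int, float]] = []
            def flush():
                if not group:
                    return
                positions = [g[0] for g in group]
                llr = float(np.mean([g[1] for g in group]))
                s, e = positions[0], positions[-1]
                seq = ref_seq[max(0, s - context) : e + 2 + context]
                fh.write(
                    f"{chrom}\t+\t{s}\t{e}\t{read_id}\t{llr:.4f}\t"
                    f"{llr:.4f}\t{0.0:.4f}\t1\t{len(positions)}\t{seq}\n"
                )
            for r in sub.itertuples():
                if group and int(r.pos) - group[-1][0] >= group_distance:
                    flush()
                    group = []
                group.append((int(r.pos), float(r.llr)))
            flush()


def write_custom_table(read_truth: pd.DataFrame, chrom: str, path: str) -> None:
    """Minimal (read, chrom, pos, probability) table for the custom dialect."""
    with open(path, "w") as fh:
        for r in read_truth.itertuples():
            p = 1.0 / (1.0 + math.exp(-r.llr))
            fh.write(f"{r.read_id}\t{chrom}\t{int(r.pos)}\t{p:.8f}\n")


def write_truth_bed(config: SimConfig, path: str) -> None:
    """True-probability intervals as BED4 (name = probability)."""
    with open(path, "w") as fh:
        for s, e, p in config.prob_intervals:
            fh.write(f"{config.chrom}\t{s}\t{e}\t{p}\n")
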
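"""Importers: BAM base-modification tags and tabular caller outputs.

All importers normalize scores to the natural-log probability ratio and
classify each call against the sample's cutoffs as it is stored.  CpG calls
on the reverse strand are collapsed onto the plus-strand C (position - 1) so
that both strands of the symmetric motif aggregate to a single site;
asymmetric motifs keep their strands separate.
"""

from __future__ import annotations

import csv
import logging
import math
import os
from dataclasses import dataclass
from typing import Optional

import pysam

from .calls import (
    CANONICAL_BASE,
    CutoffConfig,
    ImportReport,
    ModCall,
    classify,
    ml_byte_to_probability,
    probability_to_llr,
)
from .store import CallStore

logger = logging.getLogger(__name__)


def _should_collapse(motif: Optional[str], canonical: str) -> bool:
    # Collapse only the symmetric CpG case: the scored base occupies the
    # mirror-image position on both strands, so minus calls at pos map to
    # the plus-strand base at pos - 1.  Motifs like GATC/6mA have two
    # distinct adenines and must keep strands separate.
    return motif is not None and motif.upper() == "CG" and canonical == "C"


def import_bam_modcalls(
    bam_path: str,
    sample: str,
    mod_code: str = "m",
    motif: Optional[str] = "CG",
    store: Optional[CallStore] = None,
    cutoffs: Optional[CutoffConfig] = None,
    collapse_strands: Optional[bool] = None,
) -> CallStore:
    """Import per-read modification calls from a BAM with MM/ML tags.

    The BAM must be coordinate-sorted and indexed.  MM skip-count decoding
    follows the SAM base-modification convention (handled by pysam); the
    read-space positions are lifted to reference space through the CIGAR,
    dropping calls that fall in insertions or soft clips.  HP and PS tags,
    when present, populate the haplotype and phase-set fields.

    Parameters
    ----------
    mod_code:
        Single-letter SAM modification code (m = 5mC, h = 5hmC, a = 6mA).
    motif:
        Modification motif; used only to decide strand collapsing
        (``CG`` collapses minus-strand calls onto the plus-strand C).
    """
    if store is None:
        store = CallStore()
    if cutoffs is None:
        cutoffs = store.cutoffs(sample)
    canonical = CANONICAL_BASE.get(mod_code, "C")
    if collapse_strands is None:
        collapse_strands = _should_collapse(motif, canonical)

    bam = pysam.AlignmentFile(bam_path, "rb")
    if not bam.has_index():
        raise FileNotFoundError(f"BAM index missing for {bam_path}; run samtools index")

    report = ImportReport(source=str(bam_path), importer="bam")
    calls = []
    for aln in bam.fetch():
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        mods = aln.modified_bases
        if mods is None and aln.has_tag("MM"):
            # htslib rejects malformed/mismatched MM-ML pairs with mods=None
            report.n_skipped += 1
            report.warnings.append(f"read {aln.query_name}: malformed MM/ML tags")
            logger.warning("skipping read %s: malformed MM/ML tags", aln.query_name)
            continue
        if not mods:
            continue
        qpos_to_ref = dict(aln.get_aligned_pairs(matches_only=True))
        strand = "-" if aln.is_reverse else "+"
        hap = aln.get_tag("HP") if aln.has_tag("HP") else None
        ps = str(aln.get_tag("PS")) if aln.has_tag("PS") else None
        emitted_any = False
        for (canon, _mod_strand, code), items in mods.items():
            if code != mod_code or canon != canonical:
                continue  # MM sub-tag for some other base/modification
            for qpos, qual in items:
                ref_pos = qpos_to_ref.get(qpos)
                if ref_pos is None:
                    continue  # insertion / soft clip: no reference coordinate
                if qual < 0 or qual > 255:
                    report.warnings.append(
                        f"read {aln.query_name}: ML byte {qual} out of range"
                    )
                    continue
                pos, out_strand = ref_pos, strand
                if collapse_strands and strand == "-":
                    pos, out_strand = ref_pos - 1, "+"
                if pos < 0:
                    continue
                score = probability_to_llr(ml_byte_to_probability(qual))
                calls.append(
                    ModCall(
                        read_id=aln.query_name,
                        sample=sample,
                        chrom=aln.reference_name,
                        ref_pos=pos,
                        strand=out_strand,
                        mod_code=mod_code,
                        score=score,
                        call=classify(score, cutoffs),
                        haplotype=hap,
                        phase_set=ps,
                    )
                )
                emitted_any = True
        if emitted_any:
            report.n_accepted += 1
    bam.close()

    report.n_emitted = store.add_calls(calls)
    store.import_reports.append(report)
    store.record_provenance("bam", str(bam_path), sample)
    return store


# ---------------------------------------------------------------------------
# tabular dialects
# ---------------------------------------------------------------------------


@dataclass
class ColumnSpec:
    """Column layout for the custom/guppy tabular dialect (0-based indices)."""

    read_id: int
    chrom: int
    pos: int
    score: int
    strand: Optional[int] = None
    score_is_probability: bool = True
    one_based: bool = False
    has_header: bool = False
    sep: str = "\t"


#: Default layout for the guppy-style dialect: a headered TSV of
#: (read_id, chrom, strand, pos, prob_mod) with 0-based positions.
GUPPY_SPEC = ColumnSpec(
    read_id=0, chrom=1, strand=2, pos=3, score=4,
    score_is_probability=True, one_based=False, has_header=True,
)


def _find_motif_offsets(sequence: str, motif: str = "CG") -> list:
    seq = sequence.upper()
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def import_tabular(
    path: str,
    dialect: str,
    sample: str,
    store: Optional[CallStore] = None,
    column_spec: Optional[ColumnSpec] = None,
    cutoffs: Optional[CutoffConfig] = None,
    mod_code: str = "m",
    motif: Optional[str] = "CG",
) -> CallStore:
    """Import per-read calls from a tabular caller output.

    Dialects
    --------
    ``megalodon``
        Per-read text: read_id, chrm, strand, pos, mod_log_prob,
        can_log_prob, mod_base; score = mod_log_prob - can_log_prob.
    ``nanopolish``
        Methylation-call TSV; a row whose num_motifs = k covers a group of
        k CpGs and is expanded to one call per CpG, each carrying the
        row's log_lik_ratio; positions of group members are recovered by
        scanning the row's sequence context for the motif.
    ``guppy`` / ``custom``
        Generic (read name, position, probability-or-LLR) tables described
        by a :class:`ColumnSpec`; guppy defaults to :data:`GUPPY_SPEC`.

    Unparseable rows are skipped and counted in the import report attached
    to ``store.import_reports``.  Zero accepted rows is an error.
    """
    if store is None:
        store = CallStore()
    if cutoffs is None:
        cutoffs = store.cutoffs(sample)
    canonical = CANONICAL_BASE.get(mod_code, "C")
    collapse = _should_collapse(motif, canonical)

    if dialect == "guppy" and column_spec is None:
        column_spec = GUPPY_SPEC
    if dialect == "custom" and column_spec is None:
        raise ValueError("custom dialect requires a column_spec")

    report = ImportReport(source=str(path), importer=f"tabular:{dialect}")
    calls = []

    def emit(read_id, chrom, pos, strand, score):
        if collapse and strand == "-":
            pos, strand = pos - 1, "+"
        calls.append(
            ModCall(
                read_id=read_id, sample=sample, chrom=chrom, ref_pos=pos,
                strand=strand, mod_code=mod_code, score=score,
                call=classify(score, cutoffs),
            )
        )

    with open(path, newline="") as fh:
        if dialect == "megalodon":
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0] == "read_id":
                    continue
                try:
                    read_id, chrom, strand, pos = row[0], row[1], row[2], int(row[3])
                    score = float(row[4]) - float(row[5])
                    if not math.isfinite(score):
                        raise ValueError("non-finite score")
                    emit(read_id, chrom, pos, strand, score)
                    report.n_accepted += 1
                except (ValueError, IndexError) as e:
                    report.n_skipped += 1
                    report.warnings.append(f"row {reader.line_num}: {e}")
        elif dialect == "nanopolish":
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                try:
                    chrom = row["chromosome"]
                    strand = row.get("strand", "+")
                    start = int(row["start"])
                    read_id = row["read_name"]
                    llr = float(row["log_lik_ratio"])
                    n_motifs = int(row.get("num_motifs", 1))
                    if not math.isfinite(llr):
                        raise ValueError("non-finite log_lik_ratio")
                    if n_motifs > 1:
                        # anchor the group on the motif window whose span
                        # matches start..end (context flanks may contain
                        # extra motif occurrences that are not group members)
                        offsets = _find_motif_offsets(row["sequence"], motif or "CG")
                        span = int(row["end"]) - start
                        window = None
                        for i in range(len(offsets) - n_motifs + 1):
                            if offsets[i + n_motifs - 1] - offsets[i] == span:
                                window = offsets[i : i + n_motifs]
                                break
                        if window is None:
                            raise ValueError(
                                f"no {n_motifs}-motif window spanning {span} bp "
                                "in sequence context"
                            )
                        for off in window:
                            emit(read_id, chrom, start + off - window[0], strand, llr)
                    else:
                        emit(read_id, chrom, start, strand, llr)
                    report.n_accepted += 1
                except (KeyError, ValueError, TypeError) as e:
                    report.n_skipped += 1
                    report.warnings.append(f"row {reader.line_num}: {e}")
        elif dialect in ("guppy", "custom"):
            spec = column_spec
            reader = csv.reader(fh, delimiter=spec.sep)
            for i, row in enumerate(reader):
                if not row or (i == 0 and spec.has_header):
                    continue
                try:
                    read_id = row[spec.read_id]
                    chrom = row[spec.chrom]
                    pos = int(row[spec.pos]) - (1 if spec.one_based else 0)
                    strand = row[spec.strand] if spec.strand is not None else "+"
                    raw = float(row[spec.score])
                    score = probability_to_llr(raw) if spec.score_is_probability else raw
                    if not math.isfinite(score):
                        raise ValueError("non-finite score")
                    emit(read_id, chrom, pos, strand, score)
                    report.n_accepted += 1
                except (ValueError, IndexError) as e:
                    report.n_skipped += 1
                    report.warnings.append(f"row {reader.line_num}: {e}")
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")

    if report.n_accepted == 0:
        raise ValueError(f"zero accepted rows importing {path} as {dialect}")

    report.n_emitted = store.add_calls(calls)
    store.import_reports.append(report)
    store.record_provenance(f"tabular:{dialect}", str(path), sample)
    if report.n_skipped:
        logger.warning(
            "%s: skipped %d unparseable rows (%d accepted)",
            os.path.basename(str(path)), report.n_skipped, report.n_accepted,
        )
    return store
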
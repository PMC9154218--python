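"""Repeat-family composite profiles in consensus coordinates.

Highly duplicated sequences (e.g. LINE-1 or Alu copies) cannot be examined
one locus at a time; instead each genomic instance is globally aligned to a
user-supplied family consensus, per-read calls are lifted through the
alignment into consensus coordinates, and the lifted calls are pooled per
consensus position.  Minus-strand elements are reverse-complemented before
alignment so all profiles share the consensus orientation.

The alignment is Needleman–Wunsch with affine gaps (match +2, mismatch −3,
a gap of length L costs 5 + 2L) and free end gaps on the element side, so a
5'- or 3'-truncated element aligns to the corresponding stretch of the
consensus without penalty.  Elements whose alignment identity falls below a
threshold (default 0.6) are excluded as likely misassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .calls import CallState
from .segaggregate import Segment
from .seqs import Reference, motif_positions, revcomp
from .store import CallStore

logger = logging.getLogger(__name__)

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = 5.0   # charged once per gap run...
GAP_EXTEND = 2.0  # ...plus this per gap base


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    # Biopython charges open_gap_score for the first gap base and
    # extend_gap_score for each subsequent one; a length-L run therefore
    # costs (GAP_OPEN + GAP_EXTEND) + (L-1)*GAP_EXTEND = GAP_OPEN + L*GAP_EXTEND.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    # Free end gaps on the element (query) side: consensus overhang against a
    # truncated element costs nothing.
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    return aligner


@dataclass
class ConsensusMap:
    """Per-element mapping from genomic to consensus coordinates.

    ``mapping`` covers exactly the aligned (match/mismatch) columns, keyed
    by genomic position; gap columns are unmapped.  The mapping is strictly
    monotone: increasing over genomic position for plus-strand elements,
    decreasing for minus-strand ones.
    """

    element: Segment
    consensus_name: str
    consensus_length: int
    score: float
    identity: float
    mapping: Dict[int, int]


def align_to_consensus(
    element_seq: str,
    consensus_seq: str,
    min_identity: Optional[float] = None,
) -> Tuple[float, Dict[int, int], float]:
    """Globally align an element to the consensus.

    Returns (score, element_index -> consensus_index mapping over aligned
    columns, identity).  Identity is matches / aligned columns.  Returns
    ``None`` in place of the tuple when identity falls below
    ``min_identity``.
    """
    if not element_seq or not consensus_seq:
        raise ValueError("element and consensus sequences must be non-empty")
    aligner = _make_aligner()
    aln = aligner.align(consensus_seq.upper(), element_seq.upper())[0]
    cons_blocks, elem_blocks = aln.aligned
    mapping: Dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    cu, eu = consensus_seq.upper(), element_seq.upper()
    for (c0, c1), (e0, e1) in zip(cons_blocks, elem_blocks):
        for k in range(c1 - c0):
            mapping[e0 + k] = c0 + k
            aligned_cols += 1
            if cu[c0 + k] == eu[e0 + k]:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    if min_identity is not None and identity < min_identity:
        return None
    return float(aln.score), mapping, identity


def consensus_map(
    reference,
    element: Segment,
    consensus_seq: str,
    consensus_name: str = "consensus",
    min_identity: float = 0.6,
) -> Optional[ConsensusMap]:
    """Build the genomic→consensus map for one element instance.

    Minus-strand elements are reverse-complemented before alignment; the
    resulting genomic keys then decrease as consensus position increases.
    Returns None (with a log message) when identity is below threshold.
    """
    ref = Reference(reference) if not isinstance(reference, Reference) else reference
    seq = ref.fetch(element.chrom, element.start, element.end)
    if element.strand == "-":
        seq = revcomp(seq)
    res = align_to_consensus(seq, consensus_seq, min_identity=min_identity)
    if res is None:
        logger.info("element %s excluded: identity below %.2f",
                    element.label, min_identity)
        return None
    score, elem_map, identity = res
    genomic: Dict[int, int] = {}
    for ei, ci in elem_map.items():
        gpos = element.start + ei if element.strand == "+" else element.end - 1 - ei
        genomic[gpos] = ci
    return ConsensusMap(
        element=element, consensus_name=consensus_name,
        consensus_length=len(consensus_seq), score=score,
        identity=identity, mapping=genomic,
    )


@dataclass
class CompositeProfile:
    """Pooled consensus-space methylation profile for a repeat family."""

    consensus_name: str
    consensus_length: int
    motif_sites: np.ndarray            # motif positions on the consensus
    pooled: pd.DataFrame               # cons_pos, n_mod, n_unmod, n_ambig, fraction, on_motif
    element_tracks: List[Tuple[str, Dict[int, CallState]]]
    n_elements: int
    excluded: List[str] = field(default_factory=list)


def composite_profile(
    store: CallStore,
    elements: Sequence[Segment],
    consensus_seq: str,
    sample: Optional[str] = None,
    motif: str = "CG",
    offset: int = 0,
    max_elements: int = 10,
    min_identity: float = 0.6,
    reference=None,
) -> CompositeProfile:
    """Pool per-read calls from every element copy in consensus coordinates.

    Calls inside each element are lifted through its alignment; for the
    symmetric CpG motif, minus-strand elements' lifted positions are
    snapped from the consensus G onto the consensus C so both orientations
    pool at the same site.  Calls landing on consensus columns that are not
    motif sites are still pooled but flagged ``on_motif=False``.  The
    ``max_elements`` individual tracks retained are those with the highest
    classified-call coverage (ties broken by (chrom, start)).
    """
    consensus_seq = consensus_seq.upper()
    cons_sites = motif_positions(consensus_seq, motif, offset)
    site_set = set(int(p) for p in cons_sites)
    is_cpg = motif.upper() == "CG"

    pooled_counts: Dict[int, np.ndarray] = {}
    tracks = []
    excluded = []
    n_used = 0

    for elem in sorted(elements, key=lambda e: (e.chrom, e.start)):
        cmap = consensus_map(reference, elem, consensus_seq,
                             min_identity=min_identity)
        if cmap is None:
            excluded.append(elem.label)
            continue
        df = store.fetch_df(chrom=elem.chrom, start=elem.start, end=elem.end,
                            sample=sample)
        states: Dict[int, CallState] = {}
        n_classified = 0
        for r in df.itertuples():
            cpos = cmap.mapping.get(int(r.ref_pos))
            if cpos is None:
                continue  # deleted column: this copy contributes nothing here
            if is_cpg and elem.strand == "-":
                # plus-collapsed CpG C lifts to the consensus G; snap to the C
                if cpos >= 1 and consensus_seq[cpos - 1 : cpos + 1] == "CG":
                    cpos -= 1
            cnt = pooled_counts.setdefault(cpos, np.zeros(3, dtype=int))
            if r.call == "MOD":
                cnt[0] += 1
                n_classified += 1
            elif r.call == "UNMOD":
                cnt[1] += 1
                n_classified += 1
            else:
                cnt[2] += 1
            # per-element display track: majority-free, last call wins per pos
            states[cpos] = CallState(r.call)
        n_used += 1
        tracks.append((n_classified, elem, states))

    if n_used == 0:
        raise ValueError("no elements survived alignment filters")

    tracks.sort(key=lambda t: (-t[0], t[1].chrom, t[1].start))
    kept = [(e.label, s) for _, e, s in tracks[:max_elements]]

    rows = []
    for cpos in sorted(pooled_counts):
        n_mod, n_unmod, n_ambig = pooled_counts[cpos]
        cov = n_mod + n_unmod
        rows.append(
            {
                "cons_pos": cpos, "n_mod": int(n_mod), "n_unmod": int(n_unmod),
                "n_ambig": int(n_ambig),
                "fraction": (n_mod / cov) if cov else np.nan,
                "on_motif": cpos in site_set,
            }
        )
    pooled = pd.DataFrame(
        rows, columns=["cons_pos", "n_mod", "n_unmod", "n_ambig", "fraction", "on_motif"]
    )
    return CompositeProfile(
        consensus_name="consensus", consensus_length=len(consensus_seq),
        motif_sites=cons_sites, pooled=pooled, element_tracks=kept,
        n_elements=n_used, excluded=excluded,
    )
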
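"""Locus- and region-plot data: motif space, per-read matrices, smoothing.

A locus is examined in "motif space": the ordered occurrences of the
modification motif within the window define ranks 0..n-1, and every call is
placed at its site's rank.  This removes the uninformative stretches between
motif sites so that profiles are comparable across CpG-sparse and CpG-dense
sequence.  Smoothing pools classified calls in a centered boxcar window over
motif ranks (not genomic distance), truncated at the edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import segaggregate
from .calls import CallState
from .seqs import Reference, motif_positions
from .store import CallStore

logger = logging.getLogger(__name__)

#: Soft upper limit on locus width; larger windows are better served by
#: binned region profiles.
LOCUS_SOFT_LIMIT = 1_000_000


@dataclass
class MotifIndex:
    """Ordered motif-site positions in a region: the genome→motif-space map."""

    chrom: str
    start: int
    end: int
    motif: str
    offset: int
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if self.positions.size and not np.all(np.diff(self.positions) > 0):
            raise ValueError("motif positions must be strictly increasing")
        self._rank = {int(p): i for i, p in enumerate(self.positions)}

    def __len__(self) -> int:
        return int(self.positions.size)

    def rank_of(self, ref_pos: int) -> Optional[int]:
        """Motif rank of a reference position, or None if not a site."""
        return self._rank.get(int(ref_pos))


def find_motif_sites(
    reference, chrom: str, start: int, end: int, motif: str = "CG", offset: int = 0
) -> MotifIndex:
    """Scan the reference for motif sites in [start, end).

    Overlapping matches are all reported; IUPAC codes in the motif are
    honoured.  ``offset`` selects the scored base within the motif
    (e.g. 1 for the A of GATC).
    """
    ref = Reference(reference) if not isinstance(reference, Reference) else reference
    seq = ref.fetch(chrom, start, end)
    pos = motif_positions(seq, motif, offset) + start
    return MotifIndex(chrom=chrom, start=start, end=end, motif=motif,
                      offset=offset, positions=pos)


def genome_to_motifspace(index: MotifIndex, ref_pos: int) -> Optional[int]:
    """Translate a genome coordinate to its motif rank (None off-site)."""
    return index.rank_of(ref_pos)


def smoothed_profile(
    n_mod: np.ndarray, n_unmod: np.ndarray, window: int = 21
) -> np.ndarray:
    """Sliding-window methylation fraction over motif ranks.

    The fraction at rank r pools classified calls over the centered window
    of ``window`` ranks (odd, truncated at the edges):
    sum(n_mod) / (sum(n_mod) + sum(n_unmod)).  Ranks whose window contains
    no classified call yield NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    n_mod = np.asarray(n_mod, dtype=float)
    n_unmod = np.asarray(n_unmod, dtype=float)
    kernel = np.ones(window)
    mod_sum = np.convolve(n_mod, kernel, mode="same")
    tot_sum = mod_sum + np.convolve(n_unmod, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot_sum > 0, mod_sum / np.where(tot_sum > 0, tot_sum, 1), np.nan)
    return frac


@dataclass
class ReadTrack:
    """One read's calls mapped to motif ranks, for the read panel."""

    read_id: str
    sample: str
    group: str
    start: int  # leftmost call position (display extent)
    end: int    # rightmost call position + 1
    states: np.ndarray  # CallState per motif rank (NOCALL where absent)


@dataclass
class LocusData:
    """Everything the locus plot needs, already in motif space."""

    index: MotifIndex
    reads: List[ReadTrack]
    groups: List[str]
    raw_points: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]
    site_counts: Dict[str, Tuple[np.ndarray, np.ndarray]]
    smoothed: Dict[str, np.ndarray]
    window: int
    highlights: List[Tuple[int, int]] = field(default_factory=list)

    def call_matrix(self, group: Optional[str] = None) -> np.ndarray:
        """Reads × motif-sites matrix of CallState values."""
        reads = [r for r in self.reads if group is None or r.group == group]
        if not reads:
            return np.empty((0, len(self.index)), dtype=object)
        return np.array([r.states for r in reads], dtype=object)


def _group_label(sample: str, haplotype, phase_mode: str) -> str:
    if phase_mode != "tags":
        return sample
    if haplotype is None or (isinstance(haplotype, float) and np.isnan(haplotype)):
        return f"{sample}|unphased"
    return f"{sample}|hap{int(haplotype)}"


def build_locus_data(
    store: CallStore,
    reference,
    chrom: str,
    start: int,
    end: int,
    motif: str = "CG",
    offset: int = 0,
    samples: Optional[Sequence[str]] = None,
    phase_mode: str = "none",
    window: int = 21,
    highlights: Optional[Sequence[Tuple[int, int]]] = None,
) -> LocusData:
    """Assemble per-read call matrix, raw points and smoothed profiles.

    ``phase_mode="tags"`` splits each sample into hap1 / hap2 / unphased
    groups using the stored HP tags; the groups partition the reads.
    Raises if the window contains no motif site (use a region profile
    instead) and warns above the ~1 Mb soft limit.
    """
    if phase_mode not in ("none", "tags"):
        raise ValueError(f"phase_mode must be 'none' or 'tags', got {phase_mode!r}")
    if end - start > LOCUS_SOFT_LIMIT:
        logger.warning(
            "locus window %d bp exceeds ~1 Mb; consider a binned region profile",
            end - start,
        )
    index = find_motif_sites(reference, chrom, start, end, motif, offset)
    if len(index) == 0:
        raise ValueError(
            f"no {motif} sites in {chrom}:{start}-{end}; "
            "use a binned region profile for motif-free windows"
        )
    if samples is None:
        samples = store.samples

    df = store.fetch_df(chrom=chrom, start=start, end=end)
    df = df[df["sample"].isin(samples)]

    n_sites = len(index)
    reads: List[ReadTrack] = []
    groups_seen: Dict[str, None] = {}
    raw: Dict[str, list] = {}
    counts: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    for (sample, read_id), sub in df.groupby(["sample", "read_id"], sort=True):
        hap = sub["haplotype"].iloc[0]
        group = _group_label(sample, hap, phase_mode)
        groups_seen.setdefault(group, None)
        # list construction keeps the enum objects (np.full would coerce the
        # str-subclass enum to a plain numpy string)
        states = np.array([CallState.NOCALL] * n_sites, dtype=object)
        for r in sub.itertuples():
            rank = index.rank_of(r.ref_pos)
            if rank is None:
                continue  # call off the motif grid (e.g. other context)
            states[rank] = CallState(r.call)
            raw.setdefault(group, []).append((rank, r.score, r.call))
        reads.append(
            ReadTrack(
                read_id=read_id, sample=sample, group=group,
                start=int(sub["ref_pos"].min()), end=int(sub["ref_pos"].max()) + 1,
                states=states,
            )
        )

    groups = sorted(groups_seen)
    raw_points = {}
    smoothed = {}
    for g in groups:
        pts = raw.get(g, [])
        ranks = np.array([p[0] for p in pts], dtype=int)
        scores = np.array([p[1] for p in pts], dtype=float)
        states = np.array([p[2] for p in pts], dtype=object)
        raw_points[g] = (ranks, scores, states)
        n_mod = np.zeros(n_sites)
        n_unmod = np.zeros(n_sites)
        np.add.at(n_mod, ranks[states == "MOD"], 1)
        np.add.at(n_unmod, ranks[states == "UNMOD"], 1)
        counts[g] = (n_mod, n_unmod)
        smoothed[g] = smoothed_profile(n_mod, n_unmod, window)

    return LocusData(
        index=index, reads=reads, groups=groups, raw_points=raw_points,
        site_counts=counts, smoothed=smoothed, window=window,
        highlights=list(highlights or []),
    )


@dataclass
class RegionData:
    """Binned, motif-normalized profile for megabase-scale windows."""

    chrom: str
    start: int
    end: int
    bin_size: int
    bins: dict          # sample -> DataFrame from wgmeth_binned
    smoothed: dict      # sample -> (bin indices, fractions) over unmasked bins
    window: int


def build_region_data(
    store: CallStore,
    reference,
    chrom: str,
    start: int,
    end: int,
    motif: str = "CG",
    offset: int = 0,
    bin_size: Optional[int] = None,
    n_bins: Optional[int] = None,
    samples: Optional[Sequence[str]] = None,
    window: int = 5,
) -> RegionData:
    """Binned methylation profile for a large region.

    Binning delegates to :func:`methkit.segaggregate.wgmeth_binned`
    restricted to the region; masked bins (zero motif sites) are excluded
    from the smoothed series.  Give either ``bin_size`` or ``n_bins``.
    """
    if (bin_size is None) == (n_bins is None):
        raise ValueError("give exactly one of bin_size or n_bins")
    if bin_size is None:
        bin_size = max(1, int(np.ceil((end - start) / n_bins)))
    if samples is None:
        samples = store.samples
    bins = {}
    smoothed = {}
    for sample in samples:
        bdf = segaggregate.wgmeth_binned(
            store, sample, bin_size, reference, motif=motif, offset=offset,
            region=(chrom, start, end),
        )
        bins[sample] = bdf
        ok = ~bdf["masked"].to_numpy()
        frac = smoothed_profile(
            bdf.loc[ok, "n_mod"].to_numpy(), bdf.loc[ok, "n_unmod"].to_numpy(), window
        )
        smoothed[sample] = (bdf.loc[ok, "bin"].to_numpy(), frac)
    return RegionData(
        chrom=chrom, start=start, end=end, bin_size=bin_size,
        bins=bins, smoothed=smoothed, window=window,
    )
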
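"""Aggregation of classified calls over segments, bins and single sites.

Methylation fractions are per-call (matching bedMethyl semantics):
``n_mod / (n_mod + n_unmod)`` with AMBIG calls counted separately and
excluded from both numerator and denominator.  The fraction is NA where the
denominator is zero.  All intervals are 0-based half-open; a call belongs
to a segment iff ``start <= ref_pos < end``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .store import CallStore
from .seqs import Reference, motif_positions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    """A half-open genomic interval with optional name/group labels."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    group: Optional[str] = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment requires start < end: {self}")

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


def read_bed(path: str) -> list:
    """Read a BED3/4/5/6 file into :class:`Segment` records.

    Column 4 is the name; column 7 (if present) or the name's text after the
    last ``"|"`` is not interpreted — group labels for segplot come from the
    ``group`` argument of :func:`segmeth` or the BED name prefix.
    """
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            segs.append(
                Segment(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else None,
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return segs


def segmeth(
    store: CallStore,
    segments: Sequence[Segment],
    samples: Optional[Sequence[str]] = None,
    reference: Optional[Reference] = None,
    motif: str = "CG",
    offset: int = 0,
    min_coverage: int = 0,
) -> pd.DataFrame:
    """Aggregate calls over segments: one row per (segment, sample).

    Columns: chrom, start, end, name, group, sample, n_mod, n_unmod,
    n_ambig, n_reads, n_motif_sites (NaN without a reference), and
    meth_fraction (NaN where no classified calls, or below ``min_coverage``).
    A segment on a chromosome absent from the store yields a row of zeros
    with a logged warning.
    """
    if store.n_calls() == 0:
        raise ValueError("call store is empty")
    if samples is None:
        samples = store.samples
    known_chroms = set(store.chroms)
    ref = Reference(reference) if reference is not None and not isinstance(reference, Reference) else reference

    rows = []
    for seg in segments:
        if seg.chrom not in known_chroms:
            logger.warning("segment %s on chromosome absent from store", seg.label)
        n_sites = math.nan
        if ref is not None:
            n_sites = int(
                motif_positions(ref.fetch(seg.chrom, seg.start, seg.end), motif, offset).size
            )
        df = store.fetch_df(chrom=seg.chrom, start=seg.start, end=seg.end)
        for sample in samples:
            sub = df[df["sample"] == sample]
            n_mod = int((sub["call"] == "MOD").sum())
            n_unmod = int((sub["call"] == "UNMOD").sum())
            n_ambig = int((sub["call"] == "AMBIG").sum())
            cov = n_mod + n_unmod
            frac = n_mod / cov if cov > 0 and cov >= min_coverage else math.nan
            rows.append(
                {
                    "chrom": seg.chrom, "start": seg.start, "end": seg.end,
                    "name": seg.label, "group": seg.group, "sample": sample,
                    "n_mod": n_mod, "n_unmod": n_unmod, "n_ambig": n_ambig,
                    "n_reads": int(sub["read_id"].nunique()),
                    "n_motif_sites": n_sites, "meth_fraction": frac,
                }
            )
    return pd.DataFrame(rows)


def write_segmeth_table(df: pd.DataFrame, path: str) -> None:
    """Write a segmeth table as TSV: one row per segment, per-sample blocks."""
    seg_cols = ["chrom", "start", "end", "name", "group"]
    stat_cols = ["n_mod", "n_unmod", "n_ambig", "n_reads", "meth_fraction"]
    wide = df[seg_cols].drop_duplicates().reset_index(drop=True)
    for sample in sorted(df["sample"].unique()):
        sub = df[df["sample"] == sample][seg_cols + stat_cols]
        sub = sub.rename(columns={c: f"{sample}_{c}" for c in stat_cols})
        wide = wide.merge(sub, on=seg_cols, how="left")
    wide.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_segmeth_table(path: str) -> pd.DataFrame:
    """Read a wide segmeth TSV back into the tidy one-row-per-(segment,
    sample) form used by the plotting layer."""
    wide = pd.read_csv(path, sep="\t", na_values=["NA"])
    seg_cols = [c for c in ("chrom", "start", "end", "name", "group") if c in wide]
    stats = ("n_mod", "n_unmod", "n_ambig", "n_reads", "meth_fraction")
    records = {}
    for col in wide.columns:
        for stat in stats:
            if col.endswith(f"_{stat}"):
                sample = col[: -len(stat) - 1]
                records.setdefault(sample, {})[stat] = col
                break
    frames = []
    for sample, mapping in sorted(records.items()):
        sub = wide[seg_cols + list(mapping.values())].copy()
        sub.columns = seg_cols + list(mapping.keys())
        sub["sample"] = sample
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# per-site aggregation and whole-genome outputs
# ---------------------------------------------------------------------------


def per_site_stats(
    store: CallStore, sample: str, chrom: Optional[str] = None
) -> pd.DataFrame:
    """Aggregate a sample's calls per collapsed site.

    Returns one row per (chrom, ref_pos) with n_mod / n_unmod / n_ambig,
    coverage = n_mod + n_unmod and meth_fraction, sorted by (chrom, ref_pos).
    """
    df = store.fetch_df(chrom=chrom, sample=sample)
    if df.empty:
        return pd.DataFrame(
            columns=["chrom", "ref_pos", "strand", "n_mod", "n_unmod", "n_ambig",
                     "coverage", "meth_fraction", "mod_code"]
        )
    g = df.groupby(["chrom", "ref_pos"], sort=True)
    out = g.agg(
        strand=("strand", "first"),
        mod_code=("mod_code", "first"),
        n_mod=("call", lambda c: int((c == "MOD").sum())),
        n_unmod=("call", lambda c: int((c == "UNMOD").sum())),
        n_ambig=("call", lambda c: int((c == "AMBIG").sum())),
    ).reset_index()
    out["coverage"] = out["n_mod"] + out["n_unmod"]
    out["meth_fraction"] = np.where(
        out["coverage"] > 0, out["n_mod"] / out["coverage"].replace(0, np.nan), np.nan
    )
    return out.sort_values(["chrom", "ref_pos"], kind="mergesort").reset_index(drop=True)


def write_bedmethyl(sites: pd.DataFrame, path: str) -> int:
    """Write per-site aggregates as bedMethyl (BED9+2).

    Columns: chrom, start, end=start+1, name=mod code, score=min(1000,
    coverage), strand, thickStart, thickEnd, color, coverage, percent
    (integer-rounded 100*fraction).  Sites with zero classified calls are
    omitted; lines are sorted by (chrom, start).  Returns lines written.
    """
    n = 0
    rows = sites.sort_values(["chrom", "ref_pos"], kind="mergesort")
    with open(path, "w") as fh:
        for r in rows.itertuples():
            cov = int(r.n_mod + r.n_unmod)
            if cov == 0:
                continue
            pct = int(round(100.0 * r.n_mod / cov))
            start, end = int(r.ref_pos), int(r.ref_pos) + 1
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.mod_code}\t{min(1000, cov)}\t"
                f"{r.strand}\t{start}\t{end}\t0,0,0\t{cov}\t{pct}\n"
            )
            n += 1
    return n


def read_bedmethyl(path: str) -> pd.DataFrame:
    """Parse a bedMethyl file back to (chrom, start, coverage, percent)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand",
               "thickStart", "thickEnd", "color", "coverage", "percent"],
    )
    return df


def write_dss_table(sites: pd.DataFrame, path: str) -> int:
    """Write a per-sample table for differential-methylation testing (DSS).

    Header ``chr pos N X`` (tab-separated); pos is 1-based, N the classified
    coverage, X the methylated count; one row per covered site.
    """
    n = 0
    rows = sites.sort_values(["chrom", "ref_pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("chr\tpos\tN\tX\n")
        for r in rows.itertuples():
            cov = int(r.n_mod + r.n_unmod)
            if cov == 0:
                continue
            fh.write(f"{r.chrom}\t{int(r.ref_pos) + 1}\t{cov}\t{int(r.n_mod)}\n")
            n += 1
    return n


def wgmeth_binned(
    store: CallStore,
    sample: str,
    bin_size: int,
    reference: Reference,
    motif: str = "CG",
    offset: int = 0,
    chrom: Optional[str] = None,
    region: Optional[tuple] = None,
) -> pd.DataFrame:
    """Aggregate a sample's calls into fixed-size bins, motif-normalized.

    Bins tile each chromosome (or the given ``region`` = (chrom, start,
    end)) without overlap; the last partial bin is kept and flagged.  Each
    bin carries its motif-site count from the reference, and bins with zero
    motif sites are masked (no fraction).
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    ref = Reference(reference) if not isinstance(reference, Reference) else reference

    if region is not None:
        targets = [region]
    elif chrom is not None:
        targets = [(chrom, 0, ref.chrom_length(chrom))]
    else:
        targets = [(c, 0, ref.chrom_length(c)) for c in ref.chroms]

    rows = []
    for chrom_, rstart, rend in targets:
        seq = ref.fetch(chrom_, rstart, rend)
        sites = motif_positions(seq, motif, offset) + rstart
        df = store.fetch_df(chrom=chrom_, start=rstart, end=rend, sample=sample)
        pos = df["ref_pos"].to_numpy()
        call = df["call"].to_numpy()
        n_bins = int(math.ceil((rend - rstart) / bin_size))
        for i in range(n_bins):
            b0 = rstart + i * bin_size
            b1 = min(rstart + (i + 1) * bin_size, rend)
            in_bin = (pos >= b0) & (pos < b1)
            n_mod = int(((call == "MOD") & in_bin).sum())
            n_unmod = int(((call == "UNMOD") & in_bin).sum())
            n_ambig = int(((call == "AMBIG") & in_bin).sum())
            n_sites = int(((sites >= b0) & (sites < b1)).sum())
            cov = n_mod + n_unmod
            rows.append(
                {
                    "chrom": chrom_, "bin": i, "start": b0, "end": b1,
                    "n_mod": n_mod, "n_unmod": n_unmod, "n_ambig": n_ambig,
                    "n_motif_sites": n_sites,
                    "masked": n_sites == 0,
                    "partial": (b1 - b0) < bin_size,
                    "meth_fraction": (n_mod / cov) if (cov > 0 and n_sites > 0) else math.nan,
                }
            )
    return pd.DataFrame(rows)
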
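"""SQLite-backed store of per-read modified-base calls.

The store keeps one row per (sample, read, chrom, site, mod code) call with
its log-probability-ratio score and tri-state classification, plus a
per-sample cutoff table and provenance metadata.  An index on
(sample, chrom, ref_pos) makes region queries cheap; classification is held
in the table so counts are a single aggregate query, and is rewritten in
place when cutoffs are adjusted.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .calls import CallState, CutoffConfig, DEFAULT_CUTOFFS, ModCall

_SCHEMA = """
CREATE TABLE IF NOT EXISTS calls (
    read_id   TEXT NOT NULL,
    sample    TEXT NOT NULL,
    chrom     TEXT NOT NULL,
    ref_pos   INTEGER NOT NULL,
    strand    TEXT NOT NULL,
    mod_code  TEXT NOT NULL,
    score     REAL NOT NULL,
    call      TEXT NOT NULL,
    haplotype INTEGER,
    phase_set TEXT,
    PRIMARY KEY (sample, read_id, chrom, ref_pos, mod_code)
);
CREATE INDEX IF NOT EXISTS idx_calls_region ON calls (sample, chrom, ref_pos);
CREATE TABLE IF NOT EXISTS cutoffs (
    sample TEXT PRIMARY KEY,
    lo REAL NOT NULL,
    hi REAL NOT NULL
);
CREATE TABLE IF NOT EXISTS provenance (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    importer TEXT,
    source TEXT,
    sample TEXT
);
"""

_COLUMNS = (
    "read_id sample chrom ref_pos strand mod_code score call haplotype phase_set".split()
)


@dataclass
class ScoreDistribution:
    """Gridded kernel density estimate of a sample's scores, with call counts."""

    sample: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    counts: dict

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


class CallStore:
    """Indexed store of :class:`~methkit.calls.ModCall` records.

    Parameters
    ----------
    path:
        SQLite database path; the default ``":memory:"`` keeps the store
        in RAM.  A file-backed store can be reopened later with the same
        constructor.
    """

    def __init__(self, path: str = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self.import_reports: list = []

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "CallStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writing -----------------------------------------------------------

    def add_calls(self, calls: Iterable[ModCall]) -> int:
        """Insert calls; a duplicate (sample, read, chrom, pos, mod) is replaced."""
        rows = [
            (
                c.read_id, c.sample, c.chrom, int(c.ref_pos), c.strand, c.mod_code,
                float(c.score), c.call.value, c.haplotype, c.phase_set,
            )
            for c in calls
        ]
        with self._conn:
            self._conn.executemany(
                "INSERT OR REPLACE INTO calls VALUES (?,?,?,?,?,?,?,?,?,?)", rows
            )
        return len(rows)

    def record_provenance(self, importer: str, source: str, sample: str) -> None:
        with self._conn:
            self._conn.execute(
                "INSERT INTO provenance (importer, source, sample) VALUES (?,?,?)",
                (importer, source, sample),
            )

    # -- cutoffs -----------------------------------------------------------

    def cutoffs(self, sample: str) -> CutoffConfig:
        row = self._conn.execute(
            "SELECT lo, hi FROM cutoffs WHERE sample = ?", (sample,)
        ).fetchone()
        return CutoffConfig(*row) if row else DEFAULT_CUTOFFS

    def adjust_cutoffs(self, sample: str, lo: float, hi: float) -> CutoffConfig:
        """Set a sample's cutoffs and reclassify its stored calls in place."""
        cfg = CutoffConfig(lo, hi)  # validates lo < hi
        with self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO cutoffs (sample, lo, hi) VALUES (?,?,?)",
                (sample, cfg.lo, cfg.hi),
            )
            self._conn.execute(
                "UPDATE calls SET call = CASE"
                " WHEN score >= ? THEN 'MOD'"
                " WHEN score <= ? THEN 'UNMOD'"
                " ELSE 'AMBIG' END WHERE sample = ?",
                (cfg.hi, cfg.lo, sample),
            )
        return cfg

    # -- reading -----------------------------------------------------------

    @property
    def samples(self) -> list:
        return [r[0] for r in self._conn.execute("SELECT DISTINCT sample FROM calls ORDER BY sample")]

    @property
    def chroms(self) -> list:
        return [r[0] for r in self._conn.execute("SELECT DISTINCT chrom FROM calls ORDER BY chrom")]

    def n_calls(self, sample: Optional[str] = None) -> int:
        if sample is None:
            return self._conn.execute("SELECT COUNT(*) FROM calls").fetchone()[0]
        return self._conn.execute(
            "SELECT COUNT(*) FROM calls WHERE sample = ?", (sample,)
        ).fetchone()[0]

    def call_counts(self, sample: Optional[str] = None) -> dict:
        """Counts of MOD / UNMOD / AMBIG calls (for one sample or all)."""
        q = "SELECT call, COUNT(*) FROM calls"
        args: tuple = ()
        if sample is not None:
            q += " WHERE sample = ?"
            args = (sample,)
        q += " GROUP BY call"
        counts = {s: 0 for s in (CallState.MOD, CallState.UNMOD, CallState.AMBIG)}
        for call, n in self._conn.execute(q, args):
            counts[CallState(call)] = n
        return counts

    def scores(self, sample: str) -> np.ndarray:
        return np.array(
            [r[0] for r in self._conn.execute("SELECT score FROM calls WHERE sample = ?", (sample,))]
        )

    def _row_to_call(self, row: Sequence) -> ModCall:
        d = dict(zip(_COLUMNS, row))
        d["call"] = CallState(d["call"])
        return ModCall(**d)

    def query(
        self,
        chrom: str,
        start: Optional[int] = None,
        end: Optional[int] = None,
        sample: Optional[str] = None,
    ) -> list:
        """Calls on ``chrom`` with ``start <= ref_pos < end`` (half-open)."""
        q = f"SELECT {', '.join(_COLUMNS)} FROM calls WHERE chrom = ?"
        args: list = [chrom]
        if start is not None:
            q += " AND ref_pos >= ?"
            args.append(int(start))
        if end is not None:
            q += " AND ref_pos < ?"
            args.append(int(end))
        if sample is not None:
            q += " AND sample = ?"
            args.append(sample)
        q += " ORDER BY ref_pos, read_id"
        return [self._row_to_call(r) for r in self._conn.execute(q, args)]

    def fetch_df(
        self,
        chrom: Optional[str] = None,
        start: Optional[int] = None,
        end: Optional[int] = None,
        sample: Optional[str] = None,
    ) -> pd.DataFrame:
        """Same filter as :meth:`query` but as a DataFrame (for aggregation)."""
        q = f"SELECT {', '.join(_COLUMNS)} FROM calls"
        clauses, args = [], []
        if chrom is not None:
            clauses.append("chrom = ?")
            args.append(chrom)
        if start is not None:
            clauses.append("ref_pos >= ?")
            args.append(int(start))
        if end is not None:
            clauses.append("ref_pos < ?")
            args.append(int(end))
        if sample is not None:
            clauses.append("sample = ?")
            args.append(sample)
        if clauses:
            q += " WHERE " + " AND ".join(clauses)
        return pd.read_sql_query(q, self._conn, params=args)


def score_distribution(
    store: CallStore, sample: str, gridsize: int = 512
) -> ScoreDistribution:
    """Kernel density estimate of a sample's score distribution.

    Scott's-rule Gaussian KDE evaluated on a regular grid spanning the data
    range extended by four bandwidths (so that even a spike at the range
    edge keeps its tail mass on the grid), making the trapezoidal integral
    1 to within ~1e-3.  Also reports MOD/UNMOD/AMBIG counts under the
    sample's current cutoffs.
    """
    scores = store.scores(sample)
    if np.unique(scores).size < 2:
        raise ValueError(
            f"sample {sample!r} has fewer than 2 distinct scores; cannot estimate density"
        )
    kde = gaussian_kde(scores)
    bw = float(kde.factor * scores.std(ddof=1))
    lo, hi = scores.min() - 4 * bw, scores.max() + 4 * bw
    grid = np.linspace(lo, hi, gridsize)
    density = kde(grid)
    return ScoreDistribution(
        sample=sample,
        grid=grid,
        density=density,
        bandwidth=bw,
        counts=store.call_counts(sample),
    )
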
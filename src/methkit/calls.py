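"""Core types for per-read modified-base calls and their classification.

A nanopore modified-base caller emits, for each read and each occurrence of a
modifiable base, either a probability of modification (guppy, BAM ML tags) or
a log-likelihood ratio (nanopolish, megalodon).  Everything downstream works
on a single common score scale: the natural-log probability ratio

    score = ln( P(modified) / P(unmodified) )

which is 0 at p = 0.5, positive for likely-modified and negative for
likely-unmodified bases.  Calls are classified against a two-sided cutoff
pair into MOD / UNMOD / AMBIG; the middle band is deliberately discarded
from methylation fractions because scores near zero carry little evidence
either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: Probabilities are clamped into this open interval before taking the log
#: ratio so that scores stay finite.
PROB_FLOOR = 1e-6
PROB_CEIL = 1.0 - 1e-6

#: Canonical base each modification code applies to (SAM base-modification
#: codes: m = 5mC, h = 5hmC, a = 6mA).
CANONICAL_BASE = {"m": "C", "h": "C", "a": "A"}


class CallState(str, Enum):
    """Tri-state classification of a call (plus NOCALL for absent data)."""

    MOD = "MOD"
    UNMOD = "UNMOD"
    AMBIG = "AMBIG"
    NOCALL = "NOCALL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CutoffConfig:
    """Two-sided score thresholds.

    ``score <= lo`` is UNMOD, ``score >= hi`` is MOD, anything strictly
    between is AMBIG.  The three classes partition the real line.
    """

    lo: float = -2.0
    hi: float = 2.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"cutoffs require lo < hi, got lo={self.lo}, hi={self.hi}")

    def classify(self, score: float) -> CallState:
        return classify(score, self)


DEFAULT_CUTOFFS = CutoffConfig()


def classify(score: float, cutoffs: CutoffConfig = DEFAULT_CUTOFFS) -> CallState:
    """Classify a log-probability-ratio score against a cutoff pair."""
    if score >= cutoffs.hi:
        return CallState.MOD
    if score <= cutoffs.lo:
        return CallState.UNMOD
    return CallState.AMBIG


def ml_byte_to_probability(b: int) -> float:
    """Decode a SAM ML probability byte to a point probability.

    An ML byte ``b`` encodes the probability interval ``[b/256, (b+1)/256)``;
    the midpoint ``(b + 0.5) / 256`` is returned.
    """
    if not 0 <= b <= 255:
        raise ValueError(f"ML byte out of range 0-255: {b}")
    return (b + 0.5) / 256.0


def probability_to_llr(p: float, clamp: bool = True) -> float:
    """Natural-log probability ratio ln(p / (1 - p)).

    With ``clamp`` (the default) the probability is first clipped to
    ``[1e-6, 1 - 1e-6]`` so the score is always finite.
    """
    if clamp:
        p = min(max(p, PROB_FLOOR), PROB_CEIL)
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability outside (0, 1): {p}")
    return math.log(p / (1.0 - p))


def llr_to_probability(score: float) -> float:
    """Logistic inverse of :func:`probability_to_llr`."""
    return 1.0 / (1.0 + math.exp(-score))


@dataclass
class ModCall:
    """One per-read, per-site modified-base call.

    ``ref_pos`` is the 0-based reference coordinate of the modifiable base;
    for CpG calls on the reverse strand this is the plus-strand C after
    strand collapsing.  ``score`` is the natural-log probability ratio.
    """

    read_id: str
    sample: str
    chrom: str
    ref_pos: int
    strand: str
    mod_code: str
    score: float
    call: CallState
    haplotype: Optional[int] = None
    phase_set: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_pos < 0:
            raise ValueError(f"negative reference position: {self.ref_pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score: {self.score}")


@dataclass
class ImportReport:
    """Bookkeeping for a single import: rows seen, skipped and calls emitted."""

    source: str
    importer: str
    n_accepted: int = 0
    n_skipped: int = 0
    n_emitted: int = 0
    warnings: list = field(default_factory=list)
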
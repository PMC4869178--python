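"""Prepare per-transcript MIRZA scores: 3'UTR windowing for the external
biophysical model, and log-sum aggregation of its per-site output.

The biophysical scoring itself is the user's job (an external binary);
this module writes the windows it needs and aggregates what it returns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DomainError


@dataclass(frozen=True)
class UtrWindow:
    """A window of a 3'UTR: [start, end) in 0-based coordinates."""

    transcript_id: str
    start: int
    end: int
    sequence: str


def split_windows(
    utr_sequence: str,
    transcript_id: str = "",
    window: int = 50,
    step: int = 25,
) -> list[UtrWindow]:
    """Split a 3'UTR into overlapping windows (default 50 nt, step 25 nt).

    Full windows are emitted at offsets 0, step, 2*step, ... while they
    fit; if sequence remains beyond the last full window, one final
    shorter window is emitted starting one step after the last full one,
    so every base is covered and no window is shorter than `step`
    (trailing fragments are merged rather than emitted alone).
    A sequence shorter than `window` yields a single full-length window.
    """
    if not utr_sequence:
        raise DomainError("empty UTR sequence")
    if step < 1 or window < step:
        raise DomainError(f"need window >= step >= 1, got ({window}, {step})")
    n = len(utr_sequence)
    if n <= window:
        return [UtrWindow(transcript_id, 0, n, utr_sequence)]
    out: list[UtrWindow] = []
    start = 0
    while start + window <= n:
        out.append(UtrWindow(transcript_id, start, start + window,
                             utr_sequence[start:start + window]))
        start += step
    last_end = out[-1].end
    if last_end < n:
        s = out[-1].start + step
        out.append(UtrWindow(transcript_id, s, n, utr_sequence[s:n]))
    return out


def aggregate_sites(site_scores: Iterable[float]) -> float | None:
    """Per-transcript MIRZA score: sum of log site scores.

    Returns ``None`` (missing score) for an empty list — the transcript
    simply has no MIRZA sites.  Scores must be positive.
    """
    scores = list(site_scores)
    if not scores:
        return None
    total = 0.0
    for s in scores:
        if s <= 0:
            raise DomainError(f"site score must be positive, got {s}")
        total += math.log(s)
    return total


def aggregate_sites_base(site_scores: Iterable[float], base: float) -> float | None:
    """Like :func:`aggregate_sites` with an explicit log base.

    The base only rescales the result, and rank scaling downstream
    erases it; it exists for users who want to match external output.
    """
    val = aggregate_sites(site_scores)
    return None if val is None else val / math.log(base)


def write_windows_fasta(utrs: Mapping[str, str], out_path: str,
                        window: int = 50, step: int = 25) -> int:
    """Window every UTR and write a FASTA of windows; returns the count.

    Window ids are ``<transcript>|<start>-<end>`` so site scores can be
    traced back to coordinates.
    """
    records = []
    for tid, seq in utrs.items():
        for w in split_windows(seq, tid, window=window, step=step):
            records.append(
                SeqRecord(Seq(w.sequence), id=f"{tid}|{w.start}-{w.end}",
                          description="")
            )
    SeqIO.write(records, out_path, "fasta")
    return len(records)


def read_utr_fasta(path: str) -> dict[str, str]:
    """Read 3'UTR sequences from FASTA (first whitespace token as id)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def aggregate_sites_table(pairs: Iterable[tuple[str, float]]) -> dict[str, float]:
    """Aggregate (transcript_id, site score) pairs to per-transcript scores."""
    by_tid: dict[str, list[float]] = {}
    for tid, score in pairs:
        by_tid.setdefault(tid, []).append(score)
    out: dict[str, float] = {}
    for tid, scores in by_tid.items():
        val = aggregate_sites(scores)
        if val is not None:
            out[tid] = val
    return out
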
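"""Tabular input/output: prediction score tables, expression profiles,
differential-expression tables, score files, and RPKM.

All tables are tab-separated with a header row.  Missing scores are
encoded on disk as an empty cell or the literal ``NA`` (case-insensitive)
and represented in memory as ``None`` — never as a sentinel number,
because 0 is a legal score value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import DomainError, EmptyResultError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical order of the six sequence-based prediction scores.
SCORE_NAMES: tuple[str, ...] = (
    "context_plus", "pct", "mitg", "mirza", "mirza_f", "mirza_n",
)

# Header aliases accepted on disk (lower-cased before matching).
_SCORE_ALIASES: dict[str, str] = {
    "context_plus": "context_plus",
    "total_context+": "context_plus",
    "total_context_plus": "context_plus",
    "context+": "context_plus",
    "pct": "pct",
    "p_ct": "pct",
    "mitg": "mitg",
    "mirza": "mirza",
    "mirza_f": "mirza_f",
    "mirza-f": "mirza_f",
    "mirza_n": "mirza_n",
    "mirza-n": "mirza_n",
}
_TRANSCRIPT_ALIASES = ("transcript_id", "transcript", "refseq_id", "id")
_MIRNA_ALIASES = ("mirna_id", "mirna", "mir")
_NA_STRINGS = ("", "na", "nan")


@dataclass(frozen=True)
class PredictionRecord:
    """Raw sequence-based scores for one (transcript, miRNA) pair.

    Any score may be ``None`` (missing); at least one must be present.
    ``context_plus`` follows the TargetScan convention: more negative
    means stronger predicted repression.
    """

    transcript_id: str
    mirna_id: str
    context_plus: float | None = None
    pct: float | None = None
    mitg: float | None = None
    mirza: float | None = None
    mirza_f: float | None = None
    mirza_n: float | None = None

    def __post_init__(self) -> None:
        if all(getattr(self, name) is None for name in SCORE_NAMES):
            raise ValidationError(
                f"record ({self.transcript_id}, {self.mirna_id}) has no "
                "prediction score from any method"
            )

    def scores(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in SCORE_NAMES}


@dataclass
class ExpressionProfile:
    """One expression profile: transcript id -> abundance.

    Any monotone abundance measure works (log-intensity, RPKM, counts);
    downstream rank scaling erases the units.
    """

    values: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        for tid, v in self.values.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite expression for {tid!r}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, tid: str) -> float:
        return self.values[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.values


@dataclass(frozen=True)
class DiffExprRecord:
    """Differential-expression result for one transcript."""

    transcript_id: str
    log2fc: float
    t: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValidationError(
                f"fdr for {self.transcript_id!r} is {self.fdr}, outside [0, 1]"
            )


def _parse_cell(raw: object) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if s.lower() in _NA_STRINGS:
        return None
    return float(s)


def _find_column(columns: Iterable[str], aliases: Iterable[str], kind: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    raise FormatError(f"no {kind} column found among {sorted(lowered.values())}")


def read_predictions(path: str, mirna: str) -> list[PredictionRecord]:
    """Read a prediction score table and keep rows for one miRNA.

    Rows where all six scores are missing are dropped (the method only
    analyses transcripts that carry at least one TargetScan, microT-CDS
    or MIRZA score); the drop count is logged.

    Raises
    ------
    FormatError
        If no recognised score column is present.
    EmptyResultError
        If no row matches `mirna`.
    ValidationError
        On duplicate (transcript, miRNA) keys.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    tcol = _find_column(df.columns, _TRANSCRIPT_ALIASES, "transcript")
    mcol = _find_column(df.columns, _MIRNA_ALIASES, "miRNA")
    score_cols = {
        _SCORE_ALIASES[c.lower()]: c
        for c in df.columns
        if c.lower() in _SCORE_ALIASES
    }
    if not score_cols:
        raise FormatError(
            f"{path}: no recognised score column; expected one of {SCORE_NAMES}"
        )

    sub = df[df[mcol] == mirna]
    if sub.empty:
        raise EmptyResultError(f"{path}: no rows for miRNA {mirna!r}")

    records: list[PredictionRecord] = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for _, row in sub.iterrows():
        key = (row[tcol], row[mcol])
        if key in seen:
            raise ValidationError(f"duplicate prediction key {key}")
        seen.add(key)
        scores = {name: _parse_cell(row[col]) for name, col in score_cols.items()}
        if all(v is None for v in scores.values()):
            dropped += 1
            continue
        records.append(PredictionRecord(row[tcol], row[mcol], **scores))
    if dropped:
        logger.info("read_predictions(%s): dropped %d all-missing rows", path, dropped)
    return records


CollapsePolicy = Literal["max", "mean", "error"]


def read_expression(
    path: str, collapse: CollapsePolicy = "max", label: str = ""
) -> ExpressionProfile:
    """Read a two-column (id, value) expression table.

    Duplicate ids (e.g. several probesets mapping to one transcript) are
    resolved by `collapse`: ``max`` (default, the microarray convention),
    ``mean``, or ``error``.
    """
    if collapse not in ("max", "mean", "error"):
        raise ValidationError(f"unknown collapse policy {collapse!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns (id, value)")
    idc, valc = df.columns[0], df.columns[1]
    values: dict[str, list[float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tid = getattr(row, "_0", None) or row[0]
        raw = row[1]
        try:
            v = float(raw)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{i}: non-numeric expression value {raw!r}"
            ) from None
        if not math.isfinite(v):
            raise FormatError(f"{path}:{i}: non-finite expression value {raw!r}")
        values.setdefault(str(tid), []).append(v)

    collapsed: dict[str, float] = {}
    for tid, vs in values.items():
        if len(vs) > 1 and collapse == "error":
            raise ValidationError(f"{path}: duplicate id {tid!r}")
        collapsed[tid] = max(vs) if collapse == "max" else sum(vs) / len(vs)
    return ExpressionProfile(collapsed, label=label or str(path))


def rpkm(count: int, gene_length_nt: int, total_mapped: int) -> float:
    """Reads Per Kilobase of gene per Million mapped reads.

    ``count / (gene_length_nt/1000 * total_mapped/1e6)``
    """
    if gene_length_nt <= 0:
        raise DomainError(f"gene length must be positive, got {gene_length_nt}")
    if total_mapped <= 0:
        raise DomainError(f"library size must be positive, got {total_mapped}")
    if count < 0:
        raise DomainError(f"count must be non-negative, got {count}")
    return count / ((gene_length_nt / 1e3) * (total_mapped / 1e6))


def read_diffexpr(path: str) -> list[DiffExprRecord]:
    """Read a DE table with columns transcript_id, log2fc, t, fdr."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    try:
        tcol = _find_column(df.columns, _TRANSCRIPT_ALIASES, "transcript")
        lcol, scol, fcol = cols["log2fc"], cols["t"], cols["fdr"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing column {exc}") from None
    out: list[DiffExprRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        tid = row[tcol]
        if tid in seen:
            raise ValidationError(f"{path}: duplicate transcript {tid!r}")
        seen.add(tid)
        out.append(
            DiffExprRecord(tid, float(row[lcol]), float(row[scol]), float(row[fcol]))
        )
    return out


def write_scores(path: str, scores: Mapping[str, float]) -> None:
    """Write a (transcript_id, score) TSV, scores at 6 significant digits."""
    df = pd.DataFrame(
        {"transcript_id": list(scores), "score": [scores[k] for k in scores]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str) -> dict[str, float]:
    """Read a (transcript_id, score) TSV written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.empty:
        return {}
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
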
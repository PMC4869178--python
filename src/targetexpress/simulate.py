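"""Synthetic miRNA-perturbation experiments.

Each simulated experiment mirrors the structure of a real perturbation
dataset: a table of sequence-based prediction scores with per-method
missingness, an expression profile for the cellular context, a
differential-expression table, and 3'UTR sequences.  The generative
model encodes the two assumptions the classifier exploits:

* a per-transcript latent targeting affinity drives all six prediction
  scores (with method-specific noise and the field's orientation
  conventions — Total Context+ is negative-is-strong);
* the probability that a transcript is truly repressed increases with
  both its affinity and its abundance, via a logistic model
  ``P(repressed) = sigmoid(alpha + effect_score*z_score +
  effect_expr*z_expr)`` — abundant targets respond more strongly.

Expression is log-normal, spanning roughly four orders of magnitude.
Repressed transcripts receive negative t-statistics whose magnitude
grows with abundance; p-values are two-sided normal tails and FDR is
Benjamini-Hochberg.  The expected miRNA's seed word is planted in the
3'UTRs of truly repressed transcripts, so the seed-enrichment gate is
tied to ground truth.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .iodata import (SCORE_NAMES, DiffExprRecord, ExpressionProfile,
                     PredictionRecord)

#: miRNA sequence used by the simulator (a miR-1-like 5'->3' RNA).
SIM_MIRNA_SEQUENCE = "UGGAAUGUAAAGAAGUAUGUAU"
SIM_MIRNA_ID = "sim-miR-1"

_DEFAULT_MISSINGNESS: dict[str, float] = {
    "context_plus": 0.30, "pct": 0.35, "mitg": 0.30,
    "mirza": 0.25, "mirza_f": 0.25, "mirza_n": 0.25,
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the package's study conditions."""

    n_transcripts: int = 2000
    n_experiments: int = 5
    seed: int = 0
    score_missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    effect_score: float = 1.5
    effect_expr: float = 1.5
    noise_sd: float = 1.0
    frac_true_sites: float = 0.15
    utr_length_range: tuple[int, int] = (200, 600)

    def __post_init__(self) -> None:
        if self.n_transcripts < 10:
            raise DomainError("need at least 10 transcripts")
        if self.frac_true_sites * self.n_transcripts < 1:
            raise DomainError("frac_true_sites * n_transcripts < 1: no signal")
        if not 0 < self.frac_true_sites < 1:
            raise DomainError("frac_true_sites must be in (0, 1)")
        if self.noise_sd <= 0:
            raise DomainError("noise_sd must be positive")
        if self.effect_score < 0 or self.effect_expr < 0:
            raise DomainError("effect sizes must be non-negative")
        for k, v in self.score_missingness.items():
            if k not in SCORE_NAMES or not 0 <= v <= 1:
                raise DomainError(f"bad missingness entry {k!r}: {v}")
        lo, hi = self.utr_length_range
        if not 30 <= lo <= hi:
            raise DomainError("utr_length_range must be ordered and >= 30 nt")


@dataclass
class SimExperiment:
    experiment_id: str
    predictions: list[PredictionRecord]
    expression: ExpressionProfile
    diffexpr: list[DiffExprRecord]
    utrs: dict[str, str]
    truth: frozenset[str]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_experiment(
    cfg: SimConfig, experiment_id: str = "sim_0", seed: int | None = None
) -> SimExperiment:
    """Draw one complete perturbation experiment from the model above."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_transcripts
    ids = [f"NM_{i:06d}" for i in range(n)]

    # context abundance: log-normal over ~4 orders of magnitude
    log_expr = rng.normal(1.5, 1.0, size=n)
    expression = 10.0 ** log_expr

    # latent targeting affinity shared by all prediction methods
    affinity = rng.normal(0.0, 1.0, size=n)
    lam = 0.75  # method loading on the latent affinity
    raw_scores: dict[str, np.ndarray] = {}
    for name in SCORE_NAMES:
        s = lam * affinity + np.sqrt(1 - lam**2) * rng.normal(size=n)
        if name == "context_plus":
            # negative-is-strong and bounded above by 0, like the real score
            raw_scores[name] = -0.45 * np.logaddexp(0.0, s + 3.0)
        elif name == "pct":
            raw_scores[name] = _sigmoid(s)           # in [0, 1]
        elif name == "mitg":
            raw_scores[name] = _sigmoid(0.8 * s)
        else:                                        # MIRZA log-sums
            raw_scores[name] = 2.0 * s + 4.0

    miss = {name: cfg.score_missingness.get(name, 0.0) for name in SCORE_NAMES}
    missing = {
        name: rng.random(n) < p for name, p in miss.items()
    }
    # every transcript keeps at least one score
    all_missing = np.logical_and.reduce([missing[n_] for n_ in SCORE_NAMES])
    forced = rng.integers(0, len(SCORE_NAMES), size=n)
    for j, name in enumerate(SCORE_NAMES):
        missing[name] &= ~(all_missing & (forced == j))

    # repression probability rises with affinity and abundance
    z_score = (affinity - affinity.mean()) / affinity.std()
    z_expr = (log_expr - log_expr.mean()) / log_expr.std()
    alpha = np.log(cfg.frac_true_sites / (1.0 - cfg.frac_true_sites))
    p_rep = _sigmoid(alpha + cfg.effect_score * z_score
                     + cfg.effect_expr * z_expr)
    repressed = rng.random(n) < p_rep
    truth = frozenset(np.array(ids)[repressed].tolist())

    # DE statistics: abundant true targets respond more strongly.  The
    # abundance-response coupling is part of the expression effect, so
    # it scales with effect_expr and vanishes in the null model.
    t = rng.normal(0.0, 1.0, size=n) * cfg.noise_sd
    shift = -(2.2 + 0.5 * cfg.effect_expr * np.clip(z_expr, -1.5, None))
    t = np.where(repressed, t + shift, t)
    pvals = 2.0 * norm.sf(np.abs(t))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    log2fc = 0.25 * t

    # 3'UTRs, with the expected seed word planted in repressed targets
    word = _seed_word_m8(SIM_MIRNA_SEQUENCE)
    lo, hi = cfg.utr_length_range
    utrs: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    lengths = rng.integers(lo, hi + 1, size=n)
    for i, tid in enumerate(ids):
        seq = "".join(rng.choice(bases, size=int(lengths[i])))
        if repressed[i]:
            pos = int(rng.integers(0, lengths[i] - len(word) + 1))
            seq = seq[:pos] + word + seq[pos + len(word):]
        utrs[tid] = seq

    predictions = [
        PredictionRecord(
            tid, SIM_MIRNA_ID,
            **{
                name: (None if missing[name][i] else float(raw_scores[name][i]))
                for name in SCORE_NAMES
            },
        )
        for i, tid in enumerate(ids)
    ]
    profile = ExpressionProfile(
        dict(zip(ids, expression.tolist())), label=experiment_id
    )
    diffexpr = [
        DiffExprRecord(tid, float(log2fc[i]), float(t[i]), float(fdr[i]))
        for i, tid in enumerate(ids)
    ]
    return SimExperiment(experiment_id, predictions, profile, diffexpr,
                         utrs, truth)


def _seed_word_m8(mirna: str) -> str:
    rc = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}
    return "".join(rc[c] for c in reversed(mirna.upper()[1:8]))


def simulate_experiments(cfg: SimConfig) -> list[SimExperiment]:
    """Draw ``cfg.n_experiments`` experiments from sub-seeds spawned
    off ``cfg.seed`` (mutually distinct, jointly reproducible)."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_experiments)
    return [
        simulate_experiment(
            cfg, experiment_id=f"sim_{i}",
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        for i, child in enumerate(children)
    ]


def simulate_manifest(cfg: SimConfig, out_dir: str) -> str:
    """Write every experiment in the exact file formats the CLI
    consumes; returns the manifest path.

    Manifest columns: experiment_id, predictions, expression, diffexpr,
    utrs, qc (qc left blank: the gate is computed, not asserted).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for exp in simulate_experiments(cfg):
        base = os.path.join(out_dir, exp.experiment_id)
        pred_path = base + ".predictions.tsv"
        expr_path = base + ".expression.tsv"
        de_path = base + ".diffexpr.tsv"
        utr_path = base + ".utrs.fa"
        pd.DataFrame(
            [
                {"transcript_id": r.transcript_id, "mirna_id": r.mirna_id,
                 **{k: ("" if v is None else f"{v:.6g}")
                    for k, v in r.scores().items()}}
                for r in exp.predictions
            ]
        ).to_csv(pred_path, sep="\t", index=False)
        pd.DataFrame(
            {"transcript_id": list(exp.expression.values),
             "expression": [f"{v:.6g}" for v in exp.expression.values.values()]}
        ).to_csv(expr_path, sep="\t", index=False)
        pd.DataFrame(
            [
                {"transcript_id": r.transcript_id, "log2fc": f"{r.log2fc:.6g}",
                 "t": f"{r.t:.6g}", "fdr": f"{r.fdr:.6g}"}
                for r in exp.diffexpr
            ]
        ).to_csv(de_path, sep="\t", index=False)
        with open(utr_path, "w") as fh:
            for tid, seq in exp.utrs.items():
                fh.write(f">{tid}\n{seq}\n")
        rows.append(
            {"experiment_id": exp.experiment_id, "predictions": pred_path,
             "expression": expr_path, "diffexpr": de_path, "utrs": utr_path}
        )
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
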
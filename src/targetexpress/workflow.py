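"""High-level glue: turn raw experiment tables into labeled feature
matrices, run the seed-enrichment gate, and package everything for
training and cross-validation."""

from __future__ import annotations

from typing import Mapping

from .enrichment import default_cutoffs, qc_pass, seed_enrichment, seed_words
from .evaluate import Experiment
from .features import build_matrix
from .iodata import DiffExprRecord, ExpressionProfile, PredictionRecord
from .labeling import LabelConfig, assign_labels
from .simulate import SIM_MIRNA_SEQUENCE, SimExperiment


def seed_qc(
    diffexpr: list[DiffExprRecord],
    utrs: Mapping[str, str],
    mirna_sequence: str,
    alpha: float = 0.001,
) -> bool:
    """Seed-enrichment QC gate for one experiment.

    Transcripts are ranked by ascending t statistic so the
    miRNA-responsive (repressed) genes lead; each candidate seed word
    (7mer-m8 and 7mer-A1) is tested and the gate passes if any shows a
    Bonferroni-significant over-representation in the leading bins.
    """
    ranked = [r.transcript_id for r in sorted(diffexpr,
                                              key=lambda r: (r.t, r.transcript_id))
              if r.transcript_id in utrs]
    if not ranked:
        return False
    cutoffs = default_cutoffs(len(ranked))
    for word in sorted(seed_words(mirna_sequence)):
        profile = seed_enrichment(ranked, utrs, word, cutoffs)
        if qc_pass(profile, alpha=alpha):
            return True
    return False


def prepare_experiment(
    sim: SimExperiment,
    label_cfg: LabelConfig = LabelConfig(),
    mirna_sequence: str = SIM_MIRNA_SEQUENCE,
    qc_alpha: float = 0.001,
    run_qc: bool = True,
) -> Experiment:
    """Label a simulated (or loaded) experiment and build its matrix."""
    predicted = {r.transcript_id for r in sim.predictions}
    labels = assign_labels(sim.diffexpr, predicted, label_cfg)
    matrix = build_matrix(sim.predictions, sim.expression, labels,
                          experiment_id=sim.experiment_id)
    qc = (seed_qc(sim.diffexpr, sim.utrs, mirna_sequence, alpha=qc_alpha)
          if run_qc else True)
    return Experiment(sim.experiment_id, matrix, sim.expression, qc)
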
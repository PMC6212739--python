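"""Prediction and scoring of direct genomic values (DGVs).

A candidate animal's DGV is the sum of its genotype codes weighted by the
posterior-mean SNP effects.  Prediction accuracy is the Pearson correlation
between DGVs and the truth (true breeding values in simulation, pre-corrected
phenotypes in real data); prediction bias is the regression slope of DGV on
truth, with 1.0 meaning unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GenotypeData

__all__ = [
    "PredictionResult",
    "EvalSummary",
    "compute_dgv",
    "accuracy",
    "bias",
    "replicate_summary",
]


@dataclass
class PredictionResult:
    dgv: np.ndarray
    candidate_ids: np.ndarray


@dataclass
class EvalSummary:
    accuracy_mean: float
    accuracy_se: float
    bias_mean: float
    bias_se: float
    per_replicate: pd.DataFrame


def compute_dgv(geno_cand: GenotypeData, effects) -> PredictionResult:
    """DGV_i = sum_j z_ij * effect_j; fixed effects are excluded.

    ``effects`` is either a plain vector aligned with the candidate panel or a
    frame/series indexed by marker id (e.g. PosteriorChain.effects_frame()),
    in which case marker ids are checked and aligned.
    """
    if isinstance(effects, pd.DataFrame):
        effects = effects.set_index("marker_id")["effect_mean"]
    if isinstance(effects, pd.Series):
        missing = [m for m in geno_cand.marker_ids if m not in effects.index]
        if missing:
            raise ValueError(
                f"no effect estimate for markers {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        vec = effects.reindex(geno_cand.marker_ids).to_numpy(dtype=np.float64)
    else:
        vec = np.asarray(effects, dtype=np.float64)
        if vec.size != geno_cand.n_markers:
            raise ValueError(
                f"{vec.size} effects for {geno_cand.n_markers} candidate markers"
            )
    dgv = geno_cand.markers.astype(np.float64) @ vec
    return PredictionResult(dgv=dgv, candidate_ids=geno_cand.animal_ids)


def _check_pair(dgv, truth):
    dgv = np.asarray(dgv, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=np.float64).ravel()
    if dgv.size != truth.size:
        raise ValueError("DGV and truth vectors differ in length")
    if dgv.size < 3:
        raise ValueError("need at least 3 animals")
    return dgv, truth


def accuracy(dgv, truth) -> float:
    """Pearson correlation between DGVs and the truth."""
    dgv, truth = _check_pair(dgv, truth)
    if np.ptp(dgv) == 0 or np.ptp(truth) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(dgv, truth)[0])


def bias(dgv, truth, direction: str = "dgv_on_truth") -> float:
    """Regression slope measuring prediction bias (1.0 = unbiased).

    ``dgv_on_truth`` regresses DGV on the truth (cov(dgv, truth)/var(truth));
    ``truth_on_dgv`` is the conventional alternative.
    """
    dgv, truth = _check_pair(dgv, truth)
    if direction == "dgv_on_truth":
        x, yv = truth, dgv
    elif direction == "truth_on_dgv":
        x, yv = dgv, truth
    else:
        raise ValueError(f"unknown bias direction {direction!r}")
    vx = float(np.var(x))
    if vx == 0:
        raise ValueError("zero-variance predictor in the bias regression")
    return float(np.cov(yv, x, ddof=0)[0, 1] / vx)


def replicate_summary(values) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(k)) over replicate metric values."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 replicates for a mean +- SE summary")
    return float(np.mean(values)), float(np.std(values, ddof=1) / np.sqrt(values.size))


def summarize_replicates(acc_values, bias_values) -> EvalSummary:
    """Table-style summary of accuracy and bias over replicates."""
    am, ase = replicate_summary(acc_values)
    bm, bse = replicate_summary(bias_values)
    per = pd.DataFrame(
        {"replicate": np.arange(1, len(acc_values) + 1),
         "accuracy": acc_values, "bias": bias_values}
    )
    return EvalSummary(am, ase, bm, bse, per)
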
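"""The 11-gene p53-pathway predictive score and the TP53 decisional tree.

The score is the unweighted mean log2 expression of 11 p53-pathway genes
(MDM2, MDM4, PPM1D, CDKN1A, ZMAT3, CCNG1, RRM2B, BAX, BCL2, DDB2, SESN1);
a line is *high* when its score strictly exceeds 7.5 on the gcrma log2
scale (the cutoff is bound to that scale).  The decisional tree predicts a
line sensitive to MDM2 inhibition iff it is TP53 wild type AND high score;
TP53-mutant lines are predicted resistant unconditionally — no input can
make a mutant line come out predicted sensitive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import AnalysisConfig, ExpressionMatrix
from .stats import TestResult, spearman

logger = logging.getLogger("mdm2pgx")


def predictive_score(
    matrix: ExpressionMatrix, config: AnalysisConfig, partial: bool = False
) -> pd.DataFrame:
    """Per-line 11-gene score and high/low class.

    The matrix must be gene-level.  In strict mode (default) every score
    gene must be present; ``partial=True`` averages the available subset
    instead, recording ``n_genes_used`` and warning.  Class is ``high``
    iff score > config.score_cutoff strictly, ``low`` otherwise.
    """
    if matrix.level != "gene":
        raise ValueError("predictive_score requires a gene-level matrix")
    present = [g for g in config.score_genes if g in matrix.values.index]
    missing = [g for g in config.score_genes if g not in matrix.values.index]
    if missing and not partial:
        raise KeyError(f"score gene(s) missing from expression matrix: {missing}")
    if missing:
        logger.warning(
            "predictive_score: averaging %d of %d score genes (missing: %s)",
            len(present), len(config.score_genes), missing,
        )
    if not present:
        raise KeyError("none of the score genes are present")
    sub = matrix.values.loc[present]
    score = sub.mean(axis=0)
    return pd.DataFrame(
        {
            "score": score,
            "score_class": np.where(score > config.score_cutoff, "high", "low"),
            "n_genes_used": len(present),
        }
    ).rename_axis("cl_id")


def decisional_tree(
    scores: pd.DataFrame, cell_lines: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Combine TP53 status with the score into a sensitivity prediction.

    mutated -> resistant (rule "mutant"); wild type with score <= cutoff
    -> resistant ("wt_low_score"); wild type with score > cutoff ->
    sensitive ("wt_high_score").  Lines with unknown TP53 status are
    rejected by name: the tree is undefined without the status.
    """
    shared = scores.index.intersection(cell_lines.index)
    status = cell_lines.loc[shared, "tp53_status"]
    unknown = status[status == "unknown"].index.tolist()
    if unknown:
        raise ValueError(f"tp53_status unknown for line(s): {unknown[:10]}")
    score = scores.loc[shared, "score"]
    mutant = status == "mutated"
    high = score > config.score_cutoff
    predicted = np.where(~mutant & high, "sensitive", "resistant")
    rule = np.where(
        mutant, "mutant", np.where(high, "wt_high_score", "wt_low_score")
    )
    out = pd.DataFrame(
        {"predicted": predicted, "rule_fired": rule}, index=shared
    ).rename_axis("cl_id")
    assert not ((out["predicted"] == "sensitive") & mutant).any()
    return out


def evaluate(predictions: pd.DataFrame, observed: pd.Series) -> dict:
    """Confusion-matrix metrics with ``sensitive`` as the positive class.

    ``observed`` maps cl_id to the sensitive/resistant dichotomy label.
    Returns the four counts plus sensitivity = tp/(tp+fn), specificity =
    tn/(tn+fp), ppv = tp/(tp+fp), npv = tn/(tn+fn) and accuracy; a zero
    denominator yields NaN for that metric.
    """
    missing = predictions.index.difference(observed.index)
    if len(missing):
        raise ValueError(f"no observed label for line(s): {list(missing[:10])}")
    obs = observed.loc[predictions.index]
    pred = predictions["predicted"]
    tp = int(((pred == "sensitive") & (obs == "sensitive")).sum())
    fp = int(((pred == "sensitive") & (obs == "resistant")).sum())
    tn = int(((pred == "resistant") & (obs == "resistant")).sum())
    fn = int(((pred == "resistant") & (obs == "sensitive")).sum())
    return summarize_confusion(tp, fp, tn, fn)


def summarize_confusion(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Metrics from the four counts (positive class = sensitive)."""

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    n = tp + fp + tn + fn
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn, "n": n,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": ratio(tp + tn, n),
    }


def validate_external(
    scores: pd.DataFrame,
    cell_lines: pd.DataFrame,
    external: pd.DataFrame,
    config: AnalysisConfig,
    exclude: list[str] | None = None,
) -> dict:
    """Apply the frozen score cutoff and tree to an external cohort.

    ``external`` is a long-format sensitivity table for the validation
    drug.  Lines in ``exclude`` (e.g. those used to derive the score) are
    removed first; the external cohort is dichotomized at its *own*
    percentile cutoff (default 30th), not the derivation cohort's.
    Returns the performance summary, the external cutoff, per-line table,
    and the Spearman of score vs external Abs IC50 for all lines and the
    wild-type subset.
    """
    exclude = set(exclude or [])
    ext = external[~external["cl_id"].isin(exclude)]
    ext = ext[ext["cl_id"].isin(scores.index) & ext["cl_id"].isin(cell_lines.index)]
    if ext.empty:
        raise ValueError("no external lines remain after exclusion/overlap")
    from .dose_response import dichotomize  # deferred: avoids cycle at import

    cutoff, labels = dichotomize(ext, config)
    kept = pd.Index(ext["cl_id"], name="cl_id")
    tree = decisional_tree(scores.loc[kept], cell_lines.loc[kept], config)
    perf = evaluate(tree, labels)

    merged = pd.DataFrame(
        {
            "score": scores.loc[kept, "score"].to_numpy(),
            "abs_ic50_uM": ext.set_index("cl_id").loc[kept, "abs_ic50_uM"].to_numpy(),
            "tp53_status": cell_lines.loc[kept, "tp53_status"].to_numpy(),
            "predicted": tree.loc[kept, "predicted"].to_numpy(),
            "observed": labels.loc[kept].to_numpy(),
        },
        index=kept,
    )
    rho_all = spearman(merged["score"], merged["abs_ic50_uM"])
    wt = merged[merged["tp53_status"] == "wild_type"]
    rho_wt: TestResult | None = None
    if len(wt) >= 3:
        rho_wt = spearman(wt["score"], wt["abs_ic50_uM"])
    return {
        "performance": perf,
        "external_cutoff_uM": cutoff,
        "per_line": merged,
        "rho_all": rho_all,
        "rho_wt": rho_wt,
    }
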
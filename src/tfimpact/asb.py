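"""Evaluation of impact scores against allele-specific binding (ASB) labels.

ASB SNPs — heterozygous sites with significantly imbalanced ChIP reads
between alleles — are the most direct available ground truth for variant
impact predictors.  Scores are assessed as rankings: AUROC under the
Mann-Whitney convention (ties count 0.5) and AUPRC as average precision
(step interpolation).  TFs with too few labeled SNPs are skipped rather
than reported with unstable estimates.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

MIN_LABELED_SNPS = 150

ASB_LABELS = {"ASB": 1, "non-ASB": 0}


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals the Mann-Whitney U statistic divided
    by n_pos * n_neg, with tied scores contributing 0.5."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size or y.size == 0:
        raise ValueError("scores and labels must be equal-length and nonempty")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, s))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision: sum of (recall step) x (precision) over descending
    score thresholds."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if not np.any(y == 1):
        raise ValueError("no positives")
    return float(average_precision_score(y, s))


def evaluate_tf(
    asb_table: pd.DataFrame,
    score_table: Mapping[tuple[str, str], float],
    min_snps: int = MIN_LABELED_SNPS,
    missing: str = "skip",
) -> pd.DataFrame:
    """Per-TF AUROC/AUPRC report for an impact-score table.

    ``asb_table`` has columns ``snp_id``, ``tf``, ``label`` (ASB / non-ASB);
    ``score_table`` maps (snp_id, tf) to an impact score.  TFs with fewer
    than ``min_snps`` labeled SNPs are skipped with a logged reason.  A
    labeled SNP without a score is skipped with a warning (``missing="skip"``,
    default) or raises (``missing="error"``).
    """
    if missing not in ("skip", "error"):
        raise ValueError("missing must be 'skip' or 'error'")
    for col in ("snp_id", "tf", "label"):
        if col not in asb_table.columns:
            raise ValueError(f"asb_table missing column {col!r}")
    bad = set(asb_table["label"]) - set(ASB_LABELS)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected ASB / non-ASB")

    rows = []
    for tf, group in asb_table.groupby("tf", sort=True):
        n_labeled = len(group)
        if n_labeled < min_snps:
            logger.info("skipping %s: %d labeled SNPs < %d", tf, n_labeled, min_snps)
            rows.append(
                {"tf": tf, "n_snps": n_labeled, "n_pos": None, "auroc": None,
                 "auprc": None, "status": f"skipped: {n_labeled} < {min_snps} SNPs"}
            )
            continue
        scores, labels = [], []
        for rec in group.itertuples(index=False):
            key = (str(rec.snp_id), str(tf))
            if key not in score_table:
                if missing == "error":
                    raise KeyError(f"no score for labeled SNP {key}")
                logger.warning("no score for labeled SNP %s; skipped", key)
                continue
            scores.append(score_table[key])
            labels.append(ASB_LABELS[rec.label])
        if not scores:
            raise ValueError(f"{tf}: no labeled SNP has a score")
        rows.append(
            {
                "tf": tf,
                "n_snps": len(scores),
                "n_pos": int(sum(labels)),
                "auroc": auroc(scores, labels),
                "auprc": auprc(scores, labels),
                "status": "evaluated",
            }
        )
    return pd.DataFrame(rows)
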
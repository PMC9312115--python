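"""The IMAT-fraction disease biomarker and cohort-level agreement.

Per slice, the biomarker is the fraction of the muscle region occupied by
IMAT pixels, ``Area_IMAT / Area_whole-muscle``.  Severity bands follow the
clinical convention mild (0-33%), moderate (34-66%), severe (67-100%),
realized as continuous cutpoints at 1/3 and 2/3 (upper-inclusive for
mild/moderate, so every fraction in [0, 1] is classified).  Cohort-level
agreement between ground-truth and predicted fractions is an ordinary
least-squares regression plus the Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .labels import TissueLabelMap


@dataclass
class BiomarkerReport:
    subject_id: str
    imat_area: int
    muscle_area: int
    imat_fraction: float
    severity: str

    @classmethod
    def from_labels(cls, labels: TissueLabelMap, subject_id: str = "") -> "BiomarkerReport":
        imat_area = int(labels.imat_mask.sum())
        muscle_area = int(labels.muscle_mask.sum())
        frac = imat_fraction(labels)
        return cls(subject_id=subject_id, imat_area=imat_area,
                   muscle_area=muscle_area, imat_fraction=frac,
                   severity=severity_class(frac))


def imat_fraction(labels: TissueLabelMap) -> float:
    """IMAT pixel count divided by muscle-region (viable + IMAT) count."""
    muscle = labels.muscle_mask.sum()
    if muscle == 0:
        raise ValueError("empty muscle region")
    return float(labels.imat_mask.sum() / muscle)


def severity_class(fraction: float) -> str:
    """mild (<= 1/3), moderate (<= 2/3) or severe."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction <= 1.0 / 3.0:
        return "mild"
    if fraction <= 2.0 / 3.0:
        return "moderate"
    return "severe"


def cohort_agreement(gt_fractions, pred_fractions) -> tuple:
    """OLS line pred ~ gt and Pearson r; returns (slope, intercept, r)."""
    gt = np.asarray(gt_fractions, dtype=np.float64)
    pred = np.asarray(pred_fractions, dtype=np.float64)
    if gt.shape != pred.shape or gt.ndim != 1:
        raise ValueError("fraction lists must be 1-D and equally long")
    if len(gt) < 3:
        raise ValueError("need at least 3 subjects")
    if np.allclose(gt, gt[0]):
        raise ValueError("zero variance in ground-truth fractions")
    res = stats.linregress(gt, pred)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def report_table(reports: list) -> pd.DataFrame:
    """One row per BiomarkerReport."""
    return pd.DataFrame([asdict(r) for r in reports])
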
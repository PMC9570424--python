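"""Patient-level risk scoring and diagnostic evaluation.

A patient's score is the percentage of their qualified images classified
abnormal.  Diagnostic performance is assessed against the clinical
reference standard with a rank-based ROC/AUC, a Youden-index-optimal
cutoff (J = sensitivity + specificity - 1) and the resulting confusion
matrix.  The published 48-patient validation cohort — per-patient
abnormal-image percentages for the tm, a2 and tm & a2 modalities plus the
liquid-based cytology (LBC) outcome — ships as a packaged table so the
printed evaluation can be recomputed end to end.

Conventions (applied uniformly): a patient is predicted positive when the
score is >= the cutoff; candidate ROC thresholds are -inf, +inf and the
midpoints between consecutive distinct pooled scores; the reported cutoff
is the midpoint of the two distinct scores bracketing the optimal
decision boundary, rounded half-up to an integer percent; exact Youden
ties resolve toward the higher-specificity boundary (fewer false
positives).
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["PatientScore", "ROCResult", "CutoffResult", "ConfusionMatrix",
           "ScoreError", "abnormal_fraction", "positive_class", "roc_curve",
           "youden_cutoff", "classify_patients", "confusion", "sens_spec",
           "load_validation_scores", "as_patient_scores", "evaluate_modality",
           "evaluate_lbc", "MODALITY_COLUMNS"]

MODALITY_COLUMNS = {"tm": "tm_pct", "a2": "a2_pct", "tm&a2": "tma2_pct"}

_FIXTURE_NAME = "validation_cohort_scores.csv"
_FIXTURE_SHA256 = "5f01dcd51fc2bfce163df53880a3e12cac0a7f701a6d46e93eab636ff0c6d674"

_NEGATIVE_GROUPS = {"benign", "normal"}
_POSITIVE_GROUPS = {"CC", "CINII/III"}
_LESION_MARKERS = ("VIN", "VAIN")


class ScoreError(ValueError):
    """A patient cannot be scored or a curve cannot be built."""


@dataclass
class PatientScore:
    patient_id: str
    group: str
    lesion_note: str = ""
    abnormal_pct: dict | None = None     # modality -> percent

    def __post_init__(self) -> None:
        for mod, pct in (self.abnormal_pct or {}).items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(
                    f"{self.patient_id}: {mod} percentage {pct} out of range")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    scores: np.ndarray
    truth: np.ndarray


@dataclass
class CutoffResult:
    cutoff_pct: int
    youden_j: float
    bracket: tuple                      # the two scores whose midpoint it is
    sensitivity: float
    specificity: float


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def abnormal_fraction(image_labels) -> float:
    """Percent of a patient's qualified images labeled abnormal."""
    labels = list(image_labels)
    if not labels:
        raise ScoreError("patient has no qualified images and cannot be scored")
    bad = {l for l in labels} - {"normal", "abnormal"}
    if bad:
        raise ValueError(f"unrecognised image labels: {sorted(bad)}")
    return 100.0 * sum(l == "abnormal" for l in labels) / len(labels)


def positive_class(group: str, lesion_note: str = "") -> bool:
    """Clinical reference standard: is this patient truly positive?

    Cancer and high-grade CIN patients are positive; benign and normal
    are negative; follow-up patients are positive only when a new VIN or
    VaIN lesion was found.
    """
    if group in _POSITIVE_GROUPS:
        return True
    if group in _NEGATIVE_GROUPS:
        return False
    if group == "follow-up":
        note = (lesion_note or "").upper()
        return any(marker in note for marker in _LESION_MARKERS)
    raise ValueError(f"unknown clinical group {group!r}")


def roc_curve(scores, truth) -> ROCResult:
    """ROC over thresholds -inf, midpoints of distinct scores, +inf.

    Decision rule: score >= threshold means predicted positive.  AUC uses
    the rank (Mann-Whitney) formula with ties counting one half.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and truth differ in length")
    P, N = int(y.sum()), int((~y).sum())
    if P == 0 or N == 0:
        raise ScoreError("ROC needs at least one positive and one negative")

    uniq = np.unique(s)
    thresholds = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0,
                                 [np.inf]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = s >= thr
        sens[i] = (pred & y).sum() / P
        spec[i] = (~pred & ~y).sum() / N

    from scipy.stats import rankdata
    ranks = rankdata(s)
    auc = (ranks[y].sum() - P * (P + 1) / 2.0) / (P * N)
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=float(auc), scores=s, truth=y)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def youden_cutoff(roc: ROCResult) -> CutoffResult:
    """Threshold maximising J; ties prefer the higher-specificity boundary."""
    J = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, len(roc.thresholds)):
        if (J[i] > J[best] + 1e-12
                or (abs(J[i] - J[best]) <= 1e-12
                    and roc.specificity[i] > roc.specificity[best])):
            best = i
    thr = roc.thresholds[best]
    uniq = np.unique(roc.scores)
    below = uniq[uniq < thr]
    above = uniq[uniq > thr]
    if len(below) and len(above):
        lo, hi = float(below.max()), float(above.min())
    elif len(above):            # boundary below every score
        lo = hi = float(above.min())
    else:                       # boundary above every score
        lo = hi = float(below.max())
    cutoff = _round_half_up((lo + hi) / 2.0)
    return CutoffResult(cutoff_pct=cutoff, youden_j=float(J[best]),
                        bracket=(lo, hi),
                        sensitivity=float(roc.sensitivity[best]),
                        specificity=float(roc.specificity[best]))


def classify_patients(scores, cutoff: float) -> np.ndarray:
    """Predicted positive iff score >= cutoff."""
    return np.asarray(scores, dtype=np.float64) >= cutoff


def confusion(predictions, truth) -> ConfusionMatrix:
    pred = np.asarray(predictions, dtype=bool)
    y = np.asarray(truth, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth differ in length")
    return ConfusionMatrix(tp=int((pred & y).sum()),
                           fp=int((pred & ~y).sum()),
                           tn=int((~pred & ~y).sum()),
                           fn=int((~pred & y).sum()))


def sens_spec(matrix: ConfusionMatrix) -> tuple[float, float]:
    """(sensitivity %, specificity %) rounded to one decimal for reporting."""
    return (round(100.0 * matrix.sensitivity, 1),
            round(100.0 * matrix.specificity, 1))


def load_validation_scores() -> pd.DataFrame:
    """Packaged per-patient scores of the published 48-patient validation
    cohort (abnormal-image percent per modality + LBC outcome).

    The file's checksum is verified so a silently edited table cannot
    masquerade as the published one.
    """
    ref = resources.files("flimcyto").joinpath("data", _FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"validation score table checksum mismatch ({digest[:12]}...); "
            "the packaged file appears to be corrupted or modified")
    import io
    df = pd.read_csv(io.BytesIO(raw), keep_default_na=False)
    df["positive"] = [positive_class(g, n)
                      for g, n in zip(df["group"], df["lesion_note"])]
    return df


def as_patient_scores(df: pd.DataFrame) -> list:
    """PatientScore views of a validation-score table."""
    return [PatientScore(patient_id=r.patient_id, group=r.group,
                         lesion_note=r.lesion_note,
                         abnormal_pct={"tm": r.tm_pct, "a2": r.a2_pct,
                                       "tm&a2": r.tma2_pct})
            for r in df.itertuples(index=False)]


def evaluate_modality(df: pd.DataFrame, modality: str) -> dict:
    """Full ROC / Youden / confusion evaluation of one score column."""
    col = MODALITY_COLUMNS.get(modality, modality)
    if col not in df.columns:
        raise ValueError(f"no score column for modality {modality!r}")
    scores = df[col].to_numpy(dtype=float)
    truth = df["positive"].to_numpy(dtype=bool)
    roc = roc_curve(scores, truth)
    cut = youden_cutoff(roc)
    cm = confusion(classify_patients(scores, cut.cutoff_pct), truth)
    se, sp = sens_spec(cm)
    return {"modality": modality, "auc": roc.auc, "cutoff_pct": cut.cutoff_pct,
            "youden_j": cut.youden_j, "bracket": cut.bracket,
            "sensitivity_pct": se, "specificity_pct": sp,
            "confusion": cm, "roc": roc}


def evaluate_lbc(df: pd.DataFrame) -> dict:
    """Confusion of the liquid-based cytology column against the standard."""
    pred = (df["lbc_result"] == "+").to_numpy()
    truth = df["positive"].to_numpy(dtype=bool)
    cm = confusion(pred, truth)
    se, sp = sens_spec(cm)
    return {"sensitivity_pct": se, "specificity_pct": sp, "confusion": cm}
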
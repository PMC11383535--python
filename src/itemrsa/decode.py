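"""Cross-phase decoding of feature type from IRAF values.

A linear maximum-margin classifier (SVM, C = 1) is trained to separate visual
from semantic IRAFs on encoding-phase data and evaluated on retrieval-phase
data of the same ROI.  Chance level is established empirically by simulating
participants with label-independent features, and a 1-df chi-squared test
compares the observed correct/incorrect totals against the null expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class TransferResult:
    roi_id: str
    accuracy: float
    n_test: int
    correct: int


@dataclass
class ChanceTest:
    chi2: float
    df: int
    p: float
    null_mean_accuracy: float


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x.reshape(-1, 1) if x.ndim == 1 else x


def train_transfer(
    enc_samples, enc_labels, ret_samples, ret_labels,
    seed: int = 0, C: float = 1.0, roi_id: str = "roi",
) -> TransferResult:
    """Fit a linear SVM on encoding samples; score it on retrieval samples."""
    Xtr, Xte = _as_2d(enc_samples), _as_2d(ret_samples)
    ytr = np.asarray(enc_labels)
    yte = np.asarray(ret_labels)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training data must contain both feature types")
    if Xtr.shape[1] != Xte.shape[1]:
        raise ValueError("train and test dimensionality must match")
    clf = SVC(kernel="linear", C=C, random_state=seed)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    correct = int((pred == yte).sum())
    return TransferResult(roi_id, correct / len(yte), len(yte), correct)


def iraf_samples(iraf: pd.DataFrame, roi_id: str, phase: str):
    """Item-wise scalar IRAF samples and feature-type labels for one ROI/phase."""
    sub = iraf[(iraf["roi_id"] == roi_id) & (iraf["phase"] == phase)]
    wide = sub.pivot_table(
        index=["participant", "item"], columns="feature_type", values="iraf"
    ).dropna()
    X = np.concatenate([wide["visual"].to_numpy(), wide["semantic"].to_numpy()])
    y = np.array(["visual"] * len(wide) + ["semantic"] * len(wide))
    return X.reshape(-1, 1), y


def classify_all_rois(iraf: pd.DataFrame, seed: int = 0) -> list[TransferResult]:
    """Train on encoding, test on retrieval, for every ROI in the table."""
    out = []
    for roi in sorted(iraf["roi_id"].unique()):
        Xtr, ytr = iraf_samples(iraf, roi, "encoding")
        Xte, yte = iraf_samples(iraf, roi, "retrieval")
        out.append(train_transfer(Xtr, ytr, Xte, yte, seed=seed, roi_id=roi))
    return out


def simulate_null(
    n_sim: int = 1000,
    n_train: int = 100,
    n_test: int = 100,
    n_features: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Transfer accuracies for simulated participants with no label signal.

    Per simulated participant, train/test features are standard normal and
    labels are randomly assigned (balanced), so accuracy is centered on 0.5.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if min(n_train, n_test) < 4 or n_features < 1:
        raise ValueError("degenerate sample shape")
    rng = np.random.default_rng(seed)
    acc = np.empty(n_sim)
    half_tr, half_te = n_train // 2, n_test // 2
    ytr = np.array(["visual"] * half_tr + ["semantic"] * (n_train - half_tr))
    yte = np.array(["visual"] * half_te + ["semantic"] * (n_test - half_te))
    for s in range(n_sim):
        res = train_transfer(
            rng.normal(size=(n_train, n_features)),
            ytr[rng.permutation(n_train)],
            rng.normal(size=(n_test, n_features)),
            yte[rng.permutation(n_test)],
            seed=0,
        )
        acc[s] = res.accuracy
    return acc


def chance_test(correct: int, total: int, null_accuracies: np.ndarray) -> ChanceTest:
    """1-df chi-squared of observed correct/incorrect totals vs. the null.

    The expected split comes from the mean null accuracy; chi2 =
    sum (O - E)^2 / E over the two cells.
    """
    if total <= 0 or correct < 0 or correct > total:
        raise ValueError("invalid correct/total counts")
    p0 = float(np.mean(null_accuracies))
    expected = np.array([total * p0, total * (1 - p0)])
    if np.any(expected < 5):
        logger.warning("expected cell count below 5; chi-squared unreliable")
    observed = np.array([correct, total - correct], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return ChanceTest(chi2, 1, float(sps.chi2.sf(chi2, 1)), p0)
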
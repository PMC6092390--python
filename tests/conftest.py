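import numpy as np
import pytest

from octaquant import (
    ChoroidPhantomSpec,
    CohortSpec,
    EnFacePhantomSpec,
    generate_choroid_phantom,
    generate_cohort,
    generate_enface_phantom,
)


@pytest.fixture(scope="session")
def noiseless_enface():
    """Noiseless en-face phantom at the default healthy vessel fraction."""
    return generate_enface_phantom(
        EnFacePhantomSpec(vessel_fraction_target=0.35, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_choroid():
    """Noiseless choroid phantom at a healthy luminal fraction."""
    return generate_choroid_phantom(
        ChoroidPhantomSpec(true_luminal_fraction=0.69, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def reference_cohort():
    """Default six-group synthetic cohort (174 eyes)."""
    return generate_cohort(CohortSpec(seed=0))


# --- independent oracles --------------------------------------------------

def niblack_oracle(pixels: np.ndarray, radius: int, k: float, c: float,
                   polarity: str = "bright") -> np.ndarray:
    """Naive per-pixel windowed mean/SD Niblack loop (symmetric padding).

    Uses the same population-SD formula as the implementation so that on
    integer-valued images every intermediate is exact and the comparison
    can be bit-for-bit.
    """
    padded = np.pad(pixels.astype(np.float64), radius, mode="symmetric")
    h, w = pixels.shape
    n = float((2 * radius + 1) ** 2)
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            mean = win.sum() / n
            var = (win * win).sum() / n - mean * mean
            sd = np.sqrt(max(var, 0.0))
            v = float(pixels[i, j])
            if polarity == "bright":
                out[i, j] = v > mean + k * sd - c
            else:
                out[i, j] = v < mean - k * sd + c
    return out


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC by direct pairwise comparison."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def delong_brute_force(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUC variance from explicitly looped structural components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
    v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
    auc = float(np.mean([[psi(x, y) for y in neg] for x in pos]))
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def youden_exhaustive(scores: np.ndarray, labels: np.ndarray) -> float:
    """Best J over every midpoint threshold, orientation fixed by the AUC.

    Matches the ROC-curve definition of the Youden index: the curve's
    orientation is chosen once (so AUC >= 0.5), then J = max(TPR - FPR)
    over all thresholds of that curve.
    """
    oriented = -scores if mann_whitney_auc(scores, labels) < 0.5 else scores
    uniq = np.unique(oriented)
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    best = 0.0
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    for t in cands:
        pred = oriented > t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        best = max(best, sens + spec - 1.0)
    return best
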
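"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def brute_force_niblack(image: np.ndarray, window_px: int, k: float) -> np.ndarray:
    """Double-loop Niblack threshold map (population SD, symmetric edge
    padding). Kept deliberately naive and independent of the package."""
    img = np.asarray(image, dtype=float)
    r = window_px // 2
    pad = np.pad(img, r, mode="symmetric")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = pad[i : i + window_px, j : j + window_px]
            out[i, j] = win.mean() + k * win.std()
    return out


def brute_force_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive enumeration of positive-negative pairs."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = values[labels]
    neg = values[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (pos.size * neg.size)
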
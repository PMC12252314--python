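"""Independent test oracles (never routed through the code paths they check)."""

from __future__ import annotations

import numpy as np


def registration_oracle(ref_img, rot_img, mask, search=15.0, step=0.25):
    """Exhaustive rotational registration.

    Rotates ``ref_img`` over the search grid and returns the angle that
    maximises the Pearson correlation with ``rot_img`` inside the eroded
    mask.
    """
    from scipy.ndimage import binary_erosion
    from skimage.transform import rotate

    inner = binary_erosion(np.asarray(mask, bool), iterations=3)
    target = np.asarray(rot_img, np.float64)[inner]
    best_angle, best_corr = 0.0, -np.inf
    for cand in np.arange(-search, search + step / 2, step):
        r = rotate(np.asarray(ref_img, np.float64), cand, order=1,
                   preserve_range=True)
        c = np.corrcoef(r[inner], target)[0, 1]
        if c > best_corr:
            best_angle, best_corr = float(cand), c
    return best_angle


def auroc_pair_counting(scores, labels) -> float:
    """AUROC by exhaustive pair counting: (concordant + ties/2) / pairs."""
    scores = np.asarray(scores, np.float64)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1
            elif p == q:
                ties += 1
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


def confusion_tally_loop(pred, truth):
    """Per-element tally of TP/FP/TN/FN."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def mse_pixel_loop(a, b) -> float:
    """Brute-force per-pixel mean squared error."""
    a = np.asarray(a, np.float64)
    b = np.asarray(b, np.float64)
    total = 0.0
    count = 0
    for idx in np.ndindex(a.shape):
        total += (a[idx] - b[idx]) ** 2
        count += 1
    return total / count
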
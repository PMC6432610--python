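"""Independent brute-force oracles used to validate the implementation.

Deliberately simple and slow: exhaustive enumeration and textbook
formulas, written without reference to the package internals they check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def full_search_block_matching(frame_a: np.ndarray, frame_b: np.ndarray,
                               block_size: int, search_bound: int,
                               noise_threshold: float) -> np.ndarray:
    """Exhaustive mean-subtracted SAD block matching, one frame pair.

    Tries every displacement with |dy|,|dx| <= search_bound, cropping the
    displaced block to the image.  Keeps the zero vector unless some
    displacement improves the per-pixel cost by more than noise_threshold.
    Returns an (grid_h, grid_w, 2) int array of (dy, dx).
    """
    a = frame_a.astype(float)
    b = frame_b.astype(float)
    h, w = a.shape
    gh = int(np.ceil(h / block_size))
    gw = int(np.ceil(w / block_size))
    out = np.zeros((gh, gw, 2), dtype=int)
    for i in range(gh):
        for j in range(gw):
            r0, r1 = i * block_size, min((i + 1) * block_size, h)
            c0, c1 = j * block_size, min((j + 1) * block_size, w)
            best, best_cost, zero_cost = (0, 0), None, None
            for dy in range(-search_bound, search_bound + 1):
                for dx in range(-search_bound, search_bound + 1):
                    rr0, rr1 = max(r0 + dy, 0), min(r1 + dy, h)
                    cc0, cc1 = max(c0 + dx, 0), min(c1 + dx, w)
                    if rr0 >= rr1 or cc0 >= cc1:
                        continue
                    pa = a[rr0 - dy : rr1 - dy, cc0 - dx : cc1 - dx]
                    pb = b[rr0:rr1, cc0:cc1]
                    cost = np.mean(np.abs((pa - pa.mean()) - (pb - pb.mean())))
                    if (dy, dx) == (0, 0):
                        zero_cost = cost
                    if (
                        best_cost is None
                        or cost < best_cost
                        or (cost == best_cost and abs(dy) + abs(dx) < abs(best[0]) + abs(best[1]))
                    ):
                        best, best_cost = (dy, dx), cost
            if best != (0, 0) and zero_cost - best_cost <= noise_threshold:
                best = (0, 0)
            out[i, j] = best
    return out


def nearest_true_distance_bruteforce(mask: np.ndarray) -> np.ndarray:
    """O(n^2) distance from each position to the nearest True entry."""
    mask = np.asarray(mask, dtype=bool)
    n = len(mask)
    true_idx = [j for j in range(n) if mask[j]]
    out = np.empty(n, dtype=float)
    for i in range(n):
        out[i] = min((abs(i - j) for j in true_idx), default=n)
    return out


def pairwise_auc(scores, truth01) -> float:
    """Tie-corrected pairwise concordance probability."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth01, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def metric_formulas(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Textbook confusion-matrix metrics; NaN where undefined."""
    n = tp + fp + fn + tn

    def safe(num, den):
        return num / den if den else float("nan")

    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (fn + tn) * (fp + tn)) / n**2
    return {
        "precision": safe(tp, tp + fp),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "accuracy": p_o,
        "kappa": 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e),
    }


def gaussian_density_decision(x, mu_pos, mu_neg, sigma, prior_pos=0.5) -> bool:
    """Direct two-density Bayes comparison: True when the positive class
    has the larger posterior."""
    f_pos = multivariate_normal.pdf(x, mean=mu_pos, cov=sigma)
    f_neg = multivariate_normal.pdf(x, mean=mu_neg, cov=sigma)
    return prior_pos * f_pos >= (1.0 - prior_pos) * f_neg
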
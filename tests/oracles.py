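"""Independent scalar-loop reference implementations.

Every function here is written as plain nested Python loops over voxels,
deliberately sharing no code with the package's vectorized implementations,
so tests can compare the two routes.
"""

from __future__ import annotations

import math


def ce_loop(pred, truth, eps=1e-7):
    """Mean two-class cross-entropy; pred is (2, D, H, W), truth (D, H, W)."""
    total = 0.0
    n = 0
    for z in range(truth.shape[0]):
        for y in range(truth.shape[1]):
            for x in range(truth.shape[2]):
                g = int(truth[z, y, x])
                for c in (0, 1):
                    ind = 1 if g == c else 0
                    p = max(float(pred[c, z, y, x]), eps)
                    total += ind * math.log(p)
                n += 1
    return -total / n


def dice_loss_loop(pred, truth, eps=1e-5):
    inter = 0.0
    s_p = 0.0
    s_g = 0.0
    for z in range(truth.shape[0]):
        for y in range(truth.shape[1]):
            for x in range(truth.shape[2]):
                g = float(truth[z, y, x])
                p = float(pred[1, z, y, x])
                inter += g * p
                s_p += p
                s_g += g
    return 1.0 - (2.0 * inter + eps) / (s_g + s_p + eps)


def dif_mse_loop(pred, truth, dif):
    total = 0.0
    n = 0
    for z in range(truth.shape[0]):
        for y in range(truth.shape[1]):
            for x in range(truth.shape[2]):
                if int(dif[z, y, x]) == 1:
                    d = float(truth[z, y, x]) - float(pred[1, z, y, x])
                    total += d * d
                    n += 1
    return total / n if n else 0.0


def pseudo_mse_loop(pred, pseudo):
    total = 0.0
    n = 0
    for z in range(pseudo.shape[0]):
        for y in range(pseudo.shape[1]):
            for x in range(pseudo.shape[2]):
                d = float(pseudo[z, y, x]) - float(pred[1, z, y, x])
                total += d * d
                n += 1
    return total / n


def xor_loop(mask_a, mask_b):
    out = []
    for z in range(mask_a.shape[0]):
        plane = []
        for y in range(mask_a.shape[1]):
            row = []
            for x in range(mask_a.shape[2]):
                row.append(1 if int(mask_a[z, y, x]) != int(mask_b[z, y, x]) else 0)
            plane.append(row)
        out.append(plane)
    return out


def binarize_loop(pred):
    out = []
    for z in range(pred.shape[1]):
        plane = []
        for y in range(pred.shape[2]):
            row = []
            for x in range(pred.shape[3]):
                row.append(1 if float(pred[1, z, y, x]) > float(pred[0, z, y, x]) else 0)
            plane.append(row)
        out.append(plane)
    return out


def sharpen_scalar(p, T):
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    a = p ** (1.0 / T)
    b = (1.0 - p) ** (1.0 / T)
    return a / (a + b)


def confusion_loop(pred, truth):
    tp = tn = fp = fn = 0
    for z in range(truth.shape[0]):
        for y in range(truth.shape[1]):
            for x in range(truth.shape[2]):
                p = int(pred[z, y, x])
                g = int(truth[z, y, x])
                if p == 1 and g == 1:
                    tp += 1
                elif p == 0 and g == 0:
                    tn += 1
                elif p == 1 and g == 0:
                    fp += 1
                else:
                    fn += 1
    return tp, tn, fp, fn


def dice_from_counts(tp, fp, fn):
    den = 2 * tp + fp + fn
    return 2 * tp / den if den else 1.0


def metrics_from_counts(tp, tn, fp, fn):
    def ratio(a, b):
        return a / b if b else 1.0

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "jaccard": ratio(tp, tp + fp + fn),
    }
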
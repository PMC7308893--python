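"""Independent brute-force reference implementations used as test oracles.

Everything here is written as directly and naively as possible (explicit
loops, no vectorisation, no reuse of the package's own code paths), so
each oracle checks the corresponding optimised implementation rather
than mirroring it.
"""

from __future__ import annotations

import math

import numpy as np


# ----------------------------------------------------------- statistics

def mahalanobis_min_distance_loop(image, means, covariances):
    """Per-pixel min Mahalanobis distance by explicit double loops."""
    h, w, _ = image.shape
    out = np.zeros((h, w))
    invs = [np.linalg.inv(c) for c in covariances]
    for y in range(h):
        for x in range(w):
            best = math.inf
            for mean, inv in zip(means, invs):
                d = image[y, x] - mean
                best = min(best, math.sqrt(max(0.0, d @ inv @ d)))
            out[y, x] = best
    return out


def em_gmm_loop(X, k, means_init, n_iter=200, reg=1e-6):
    """Plain EM for a full-covariance Gaussian mixture, fixed init."""
    n, d = X.shape
    means = np.array(means_init, dtype=float)
    covs = np.array([np.eye(d) * 0.01 for _ in range(k)])
    weights = np.full(k, 1.0 / k)
    for _ in range(n_iter):
        # E step
        resp = np.zeros((n, k))
        for j in range(k):
            inv = np.linalg.inv(covs[j])
            det = np.linalg.det(covs[j])
            diff = X - means[j]
            expo = -0.5 * np.einsum("ij,jk,ik->i", diff, inv, diff)
            resp[:, j] = weights[j] * np.exp(expo) / np.sqrt((2 * np.pi) ** d * det)
        resp /= resp.sum(axis=1, keepdims=True)
        # M step
        nk = resp.sum(axis=0)
        weights = nk / n
        for j in range(k):
            means[j] = resp[:, j] @ X / nk[j]
            diff = X - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j] + reg * np.eye(d)
    return weights, means, covs


def lloyd_kmeans_loop(X, centers_init, n_iter=100):
    """Plain Lloyd iterations from a fixed initialisation."""
    centers = np.array(centers_init, dtype=float)
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for j in range(len(centers)):
            members = X[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
    return centers


# ----------------------------------------------------------- morphology

def erosion_loop(mask, footprint):
    """Set-based erosion; out-of-image counts as background-neutral only
    for pixels whose footprint stays inside (fixtures keep a margin)."""
    h, w = mask.shape
    fh, fw = footprint.shape
    cy, cx = fh // 2, fw // 2
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy in range(fh):
                for dx in range(fw):
                    if not footprint[dy, dx]:
                        continue
                    yy, xx = y + dy - cy, x + dx - cx
                    if 0 <= yy < h and 0 <= xx < w:
                        if not mask[yy, xx]:
                            ok = False
                    # outside the image: treated as foreground (ignored)
            out[y, x] = ok
    return out


def dilation_loop(mask, footprint):
    h, w = mask.shape
    fh, fw = footprint.shape
    cy, cx = fh // 2, fw // 2
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            hit = False
            for dy in range(fh):
                for dx in range(fw):
                    if not footprint[dy, dx]:
                        continue
                    yy, xx = y - (dy - cy), x - (dx - cx)
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                        hit = True
            out[y, x] = hit
    return out


def opening_loop(mask, footprint):
    return dilation_loop(erosion_loop(mask, footprint), footprint)


def closing_loop(mask, footprint):
    return erosion_loop(dilation_loop(mask, footprint), footprint)


# ---------------------------------------------------------- convolution

def correlate_reflect_loop(image, kernel):
    """Direct spatial correlation with symmetric (reflect) borders."""
    kh, kw = kernel.shape
    assert kh % 2 == 1 and kw % 2 == 1
    padded = np.pad(image, ((kh // 2, kh // 2), (kw // 2, kw // 2)), mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(kh):
                for dx in range(kw):
                    acc += padded[y + dy, x + dx] * kernel[dy, dx]
            out[y, x] = acc
    return out


# ------------------------------------------------------------ detection

def nms_loop(boxes, scores, iou_threshold):
    """Greedy non-maximum suppression, list-based reference."""
    remaining = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            i for i in remaining if iou_loop(boxes[best], boxes[i]) <= iou_threshold
        ]
    return kept


def iou_loop(a, b):
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def greedy_match_loop(det_boxes, det_scores, truth_boxes, iou_threshold):
    """Greedy score-descending detection-truth matching, reference."""
    order = sorted(range(len(det_boxes)), key=lambda i: (-det_scores[i], i))
    free = list(range(len(truth_boxes)))
    tp = 0
    for di in order:
        best_iou, best_t = 0.0, None
        for ti in free:
            iou = iou_loop(det_boxes[di], truth_boxes[ti])
            if iou > best_iou:
                best_iou, best_t = iou, ti
        if best_t is not None and best_iou >= iou_threshold:
            tp += 1
            free.remove(best_t)
    return tp, len(det_boxes) - tp, len(truth_boxes) - tp


def confusion_loop(true_labels, pred_labels, classes):
    counts = [[0, 0], [0, 0]]
    for t, p in zip(true_labels, pred_labels):
        counts[classes.index(t)][classes.index(p)] += 1
    out = [[math.nan, math.nan], [math.nan, math.nan]]
    for i in range(2):
        row_sum = counts[i][0] + counts[i][1]
        if row_sum:
            out[i] = [counts[i][0] / row_sum, counts[i][1] / row_sum]
    return np.array(out)


# -------------------------------------------------------- triangulation

def triangulate_grid_search(observations, centre, half_extent=3.0, step=0.02):
    """Dense grid search minimising RMS perpendicular ray distance."""
    best, best_pt = math.inf, None
    east0, north0 = centre
    es = np.arange(east0 - half_extent, east0 + half_extent, step)
    ns = np.arange(north0 - half_extent, north0 + half_extent, step)
    rays = []
    for pose, bearing in observations:
        theta = math.radians(bearing)
        rays.append((pose.east, pose.north, math.cos(theta), -math.sin(theta)))
    for e in es:
        for n in ns:
            acc = 0.0
            for px, py, nx, ny in rays:
                d = nx * (e - px) + ny * (n - py)
                acc += d * d
            if acc < best:
                best, best_pt = acc, (e, n)
    return best_pt, math.sqrt(best / len(rays))


# ------------------------------------------------------------------ svm

def hard_margin_svm_qp(X, y):
    """Maximum-margin separator via constrained optimisation (SLSQP)."""
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    signs = np.where(np.asarray(y) > 0, 1.0, -1.0)
    d = X.shape[1]

    def objective(p):
        return 0.5 * (p[:d] @ p[:d])

    constraints = [
        {"type": "ineq", "fun": (lambda p, i=i: signs[i] * (X[i] @ p[:d] + p[d]) - 1.0)}
        for i in range(len(X))
    ]
    best = None
    for w0 in (np.ones(d + 1), np.array([1.0, -1.0, 0.0])[: d + 1]):
        res = minimize(objective, w0, constraints=constraints, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-12})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    return best.x[:d], best.x[d]
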
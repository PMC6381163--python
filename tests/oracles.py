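"""Independent brute-force oracles for the texture matrices and metrics.

Everything here is deliberately naive (explicit Python loops, exhaustive
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

OFFSETS_BY_ANGLE = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_by_enumeration(levels, mask, n_levels, angles=(0, 45, 90, 135), distance=1):
    """Count every in-mask pixel pair at the given offsets, both directions."""
    rows, cols = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for ang in angles:
        dr, dc = OFFSETS_BY_ANGLE[ang]
        dr, dc = dr * distance, dc * distance
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                    counts[levels[r, c], levels[r2, c2]] += 1
                    counts[levels[r2, c2], levels[r, c]] += 1
    return counts


def haralick_by_double_loop(p):
    """The eight descriptors via explicit double summation."""
    G = p.shape[0]
    energy = contrast = idm = entropy = 0.0
    px = [sum(p[i][j] for j in range(G)) for i in range(G)]
    py = [sum(p[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    sd_x = sum((i - mu_x) ** 2 * px[i] for i in range(G)) ** 0.5
    sd_y = sum((j - mu_y) ** 2 * py[j] for j in range(G)) ** 0.5
    cross = 0.0
    for i in range(G):
        for j in range(G):
            v = p[i][j]
            energy += v * v
            contrast += (i - j) ** 2 * v
            idm += v / (1 + (i - j) ** 2)
            cross += i * j * v
            if v > 0:
                entropy -= v * np.log2(v)
    correlation = (cross - mu_x * mu_y) / (sd_x * sd_y) if sd_x * sd_y > 0 else 0.0
    variance = sum((i - mu_x) ** 2 * px[i] for i in range(G))
    psum = [0.0] * (2 * G - 1)
    for i in range(G):
        for j in range(G):
            psum[i + j] += p[i][j]
    sum_average = sum(k * psum[k] for k in range(2 * G - 1))
    sum_entropy = -sum(v * np.log2(v) for v in psum if v > 0)
    return {
        "glcm_energy": energy, "glcm_contrast": contrast,
        "glcm_correlation": correlation, "glcm_inverse_difference_moment": idm,
        "glcm_entropy": entropy, "glcm_variance": variance,
        "glcm_sum_average": sum_average, "glcm_sum_entropy": sum_entropy,
    }


def runs_by_scanning(levels, mask, angle):
    """All (level, length) runs along one angle, by walking every line."""
    if angle == 90:
        levels, mask = levels.T, mask.T
    runs = []
    for lv_line, m_line in zip(levels, mask):
        c = 0
        n = len(lv_line)
        while c < n:
            if not m_line[c]:
                c += 1
                continue
            start = c
            while c + 1 < n and m_line[c + 1] and lv_line[c + 1] == lv_line[start]:
                c += 1
            runs.append((int(lv_line[start]), c - start + 1))
            c += 1
    return runs


def glrlm_by_scanning(levels, mask, n_levels, angles=(0, 90)):
    """Galloway features per angle from enumerated runs, averaged."""
    n_pixels = int(np.sum(mask))
    feats = []
    for ang in angles:
        runs = runs_by_scanning(levels, mask, ang)
        n_runs = len(runs)
        sre = sum(1.0 / r**2 for _, r in runs) / n_runs
        lre = sum(float(r**2) for _, r in runs) / n_runs
        by_level = {}
        by_length = {}
        for g, r in runs:
            by_level[g] = by_level.get(g, 0) + 1
            by_length[r] = by_length.get(r, 0) + 1
        gln = sum(v**2 for v in by_level.values()) / n_runs
        rln = sum(v**2 for v in by_length.values()) / n_runs
        feats.append({"glrlm_sre": sre, "glrlm_lre": lre, "glrlm_gln": gln,
                      "glrlm_rln": rln, "glrlm_rp": n_runs / n_pixels})
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


def ngldm_by_counting(levels, mask, n_levels, distance=1, tolerance=0):
    """Q[g, k] by walking every interior pixel and counting its neighbors."""
    rows, cols = levels.shape
    n_neigh = (2 * distance + 1) ** 2 - 1
    Q = np.zeros((n_levels, n_neigh + 1))
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            neigh = []
            interior = True
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2]):
                        interior = False
                    else:
                        neigh.append(levels[r2, c2])
            if not interior:
                continue
            k = sum(1 for v in neigh if abs(int(v) - int(levels[r, c])) <= tolerance)
            Q[levels[r, c], k] += 1
    return Q


def glgcm_descriptors_by_double_loop(p):
    """The fifteen gray-gradient descriptors via explicit summation."""
    Gg, Gs = p.shape
    pg = [sum(p[g][s] for s in range(Gs)) for g in range(Gg)]
    ps = [sum(p[g][s] for g in range(Gg)) for s in range(Gs)]
    mu_g = sum(g * pg[g] for g in range(Gg))
    mu_s = sum(s * ps[s] for s in range(Gs))
    var_g = sum((g - mu_g) ** 2 * pg[g] for g in range(Gg))
    var_s = sum((s - mu_s) ** 2 * ps[s] for s in range(Gs))
    out = {
        "glgcm_gray_nonuniformity": sum(v**2 for v in pg),
        "glgcm_gradient_nonuniformity": sum(v**2 for v in ps),
        "glgcm_gray_mean": mu_g, "glgcm_gradient_mean": mu_s,
        "glgcm_gray_variance": var_g, "glgcm_gradient_variance": var_s,
        "glgcm_gray_entropy": -sum(v * np.log2(v) for v in pg if v > 0),
        "glgcm_gradient_entropy": -sum(v * np.log2(v) for v in ps if v > 0),
    }
    sge = lge = energy = mixed = inertia = idm = cross = 0.0
    for g in range(Gg):
        for s in range(Gs):
            v = p[g][s]
            sge += v / (s + 1) ** 2
            lge += v * (s + 1) ** 2
            energy += v * v
            inertia += (g - s) ** 2 * v
            idm += v / (1 + (g - s) ** 2)
            cross += (g - mu_g) * (s - mu_s) * v
            if v > 0:
                mixed -= v * np.log2(v)
    corr = cross / (var_g * var_s) ** 0.5 if var_g > 0 and var_s > 0 else 0.0
    out.update({"glgcm_small_gradient_emphasis": sge,
                "glgcm_large_gradient_emphasis": lge,
                "glgcm_energy": energy, "glgcm_correlation": corr,
                "glgcm_mixed_entropy": mixed, "glgcm_inertia": inertia,
                "glgcm_inverse_difference_moment": idm})
    return out


def auc_by_mann_whitney(y, scores):
    """AUC as the normalized Mann-Whitney U with midrank ties."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    u = 0.0
    for a in pos:
        for b in neg:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u / (len(pos) * len(neg))


def icc21_by_anova(x):
    """ICC(2,1) from explicitly computed two-way ANOVA mean squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
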
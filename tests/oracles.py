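"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plainly as possible (explicit loops,
enumeration, direct summation) and shares no code with the package.
"""

import itertools

import numpy as np


def regional_maxima_bruteforce(matrix):
    """Regional maxima by exhaustive plateau BFS.

    A regional maximum is a connected (8-neighborhood) plateau of equal
    values none of whose pixels has a strictly greater neighbor. Returns a
    sorted list of (row, col, value) at each plateau's grid-rounded centroid
    (snapped to the nearest plateau pixel when the centroid of a concave
    plateau falls outside it).
    """
    matrix = np.asarray(matrix, dtype=float)
    nr, nc = matrix.shape

    def neighbors(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    yield rr, cc

    seen = np.zeros((nr, nc), dtype=bool)
    out = []
    for r in range(nr):
        for c in range(nc):
            if seen[r, c]:
                continue
            # flood the full equal-value plateau containing (r, c)
            val = matrix[r, c]
            comp = [(r, c)]
            seen[r, c] = True
            queue = [(r, c)]
            has_greater_neighbor = False
            while queue:
                cur = queue.pop()
                for nb in neighbors(*cur):
                    if matrix[nb] > val:
                        has_greater_neighbor = True
                    elif matrix[nb] == val and not seen[nb]:
                        seen[nb] = True
                        comp.append(nb)
                        queue.append(nb)
            if has_greater_neighbor:
                continue
            comp.sort()  # row-major
            rs = [p[0] for p in comp]
            cs = [p[1] for p in comp]
            rc = int(np.round(sum(rs) / len(rs)))
            cc_ = int(np.round(sum(cs) / len(cs)))
            if (rc, cc_) not in comp:
                # concave plateau: report the component pixel nearest the
                # centroid (first in row-major order on ties)
                rc, cc_ = min(comp, key=lambda p: (p[0] - rc) ** 2
                              + (p[1] - cc_) ** 2)
            out.append((rc, cc_, matrix[comp[0]]))
    return sorted(out)


def fwhm_bruteforce(values, axis, peak_idx):
    """FWHM by linear scan with interpolated crossings; edge doubling rule.

    Returns (width, edge_flag) or None when both sides are cut.
    """
    half = values[peak_idx] / 2.0

    def half_width(direction):
        prev = peak_idx
        i = peak_idx + direction
        while 0 <= i < len(values):
            if values[i] < half:
                x = axis[prev] + (axis[i] - axis[prev]) * (
                    (values[prev] - half) / (values[prev] - values[i]))
                return abs(x - axis[peak_idx])
            prev = i
            i += direction
        return None

    left, right = half_width(-1), half_width(+1)
    if left is None and right is None:
        return None
    if left is None:
        return 2 * right, True
    if right is None:
        return 2 * left, True
    return left + right, False


def auroc_bruteforce(values, labels):
    """Mann-Whitney AUROC by exhaustive pair counting (half credit to ties)."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    score = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                score += 1.0
            elif p == q:
                score += 0.5
    return score / (len(pos) * len(neg))


def signed_rank_left_p_enumeration(diffs):
    """Exact left-tailed one-sample signed-rank p by enumerating all 2^n sign
    assignments (no ties/zeros assumed)."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_obs = ranks[diffs > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(rk for rk, s in zip(ranks, signs) if s)
        if w <= w_obs:
            count += 1
    return count / 2**n


def friedman_chi2_formula(matrix):
    """Friedman chi-square by the rank formula (no ties assumed).

    matrix: datasets (blocks) x treatments.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.argsort(np.argsort(matrix, axis=1), axis=1) + 1.0
    rbar = ranks.mean(axis=0)
    return 12.0 * n / (k * (k + 1)) * ((rbar - (k + 1) / 2.0) ** 2).sum()


def sliding_occurrence_bruteforce(times_by_trial, starts, win_ms):
    """P(>=1 event in [s, s+win)) per window, by direct recount."""
    probs = []
    for s in starts:
        hits = 0
        for t in times_by_trial:
            if any(s <= ev < s + win_ms for ev in t):
                hits += 1
        probs.append(hits / len(times_by_trial))
    return np.array(probs)


def morlet_conv_direct(signal, fs, f0, m):
    """Direct-summation complex Morlet convolution ('same', zero padding)."""
    sigma_t = m / (2 * np.pi * f0)
    half = int(np.ceil(5 * sigma_t * fs))
    tw = np.arange(-half, half + 1) / fs
    amp = 1.0 / (sigma_t * np.sqrt(2 * np.pi))
    w = amp * np.exp(-tw**2 / (2 * sigma_t**2)) * np.exp(2j * np.pi * f0 * tw)
    n = len(signal)
    out = np.zeros(n, dtype=complex)
    for i in range(n):
        acc = 0.0 + 0.0j
        for k in range(len(w)):
            j = i - (k - half)
            if 0 <= j < n:
                acc += signal[j] * w[k]
        out[i] = acc
    return out


def survival_bruteforce(powers, grid):
    """1 - CDF by direct counting."""
    powers = list(powers)
    return np.array([sum(p > g for p in powers) / len(powers) for g in grid])
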
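"""Literal, loop-based reference implementations used as test oracles.

Everything here is deliberately written with explicit Python loops,
``math`` and ``colorsys`` — no vectorization, no scipy filters — so it is
an independent check of the package's vectorized implementations.
"""

import math


def _pixels(arr):
    h, w, _ = arr.shape
    for y in range(h):
        for x in range(w):
            yield tuple(int(v) for v in arr[y, x])


def _hsv(r, g, b):
    """(hue degrees, saturation 0-1, value 0-1), standard hexcone formulas."""
    r_, g_, b_ = r / 255.0, g / 255.0, b / 255.0
    v = max(r_, g_, b_)
    c = v - min(r_, g_, b_)
    s = 0.0 if v == 0 else c / v
    if c == 0:
        h = 0.0
    elif v == r_:
        h = ((g_ - b_) / c) % 6.0 * 60.0
    elif v == g_:
        h = ((b_ - r_) / c + 2.0) * 60.0
    else:
        h = ((r_ - g_) / c + 4.0) * 60.0
    return h, s, v


def _mean_var(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, var


def _luminance(r, g, b):
    return 0.299 * r + 0.587 * g + 0.114 * b


def oracle_channel_stats(arr):
    reds, greens, blues, sats, vals = [], [], [], [], []
    for r, g, b in _pixels(arr):
        reds.append(float(r))
        greens.append(float(g))
        blues.append(float(b))
        _, s, v = _hsv(r, g, b)
        sats.append(s * 255.0)
        vals.append(v * 255.0)
    out = {}
    for name, vals_ in (
        ("red", reds), ("green", greens), ("blue", blues),
        ("saturation", sats), ("value", vals),
    ):
        mean, var = _mean_var(vals_)
        out[f"{name}_mean"] = mean
        out[f"{name}_variance"] = var
    return out


def oracle_brightness(arr):
    lums = [_luminance(r, g, b) for r, g, b in _pixels(arr)]
    return sum(lums) / len(lums)


def oracle_colorfulness(arr):
    rg = [float(r) - g for r, g, b in _pixels(arr)]
    yb = [0.5 * (r + g) - b for r, g, b in _pixels(arr)]
    _, var_rg = _mean_var(rg)
    _, var_yb = _mean_var(yb)
    mean_rg = sum(rg) / len(rg)
    mean_yb = sum(yb) / len(yb)
    return math.sqrt(var_rg + var_yb) + 0.3 * math.sqrt(mean_rg**2 + mean_yb**2)


def oracle_naturalness(arr):
    groups = {
        "skin": ((25.0, 70.0), (0.76, 0.52)),
        "grass": ((95.0, 135.0), (0.81, 0.53)),
        "sky": ((185.0, 260.0), (0.43, 0.22)),
    }
    members = {k: [] for k in groups}
    for r, g, b in _pixels(arr):
        lum = _luminance(r, g, b) / 255.0 * 100.0
        hue, s, _ = _hsv(r, g, b)
        if not (20.0 <= lum <= 80.0 and s > 0.1):
            continue
        for name, ((lo, hi), _) in groups.items():
            if lo <= hue <= hi:
                members[name].append(s)
    total, weighted = 0, 0.0
    for name, ((_, _), (mu, sigma)) in groups.items():
        sats = members[name]
        if not sats:
            continue
        s_bar = sum(sats) / len(sats)
        score = math.exp(-0.5 * ((s_bar - mu) / sigma) ** 2)
        weighted += len(sats) * score
        total += len(sats)
    return weighted / total if total else 0.0


def oracle_contrast(arr, mode="sd"):
    lums = [_luminance(r, g, b) for r, g, b in _pixels(arr)]
    _, var = _mean_var(lums)
    sd = math.sqrt(var)
    return sd if mode == "sd" else sd / len(lums)


def oracle_rgb_contrast(arr):
    stats = oracle_channel_stats(arr)
    return math.sqrt(
        stats["red_variance"] + stats["green_variance"] + stats["blue_variance"]
    )


def oracle_sharpness(arr, aggregate="sum"):
    h, w, _ = arr.shape
    lum = [[_luminance(*arr[y, x]) for x in range(w)] for y in range(h)]

    def at(y, x):  # replicate borders
        return lum[min(max(y, 0), h - 1)][min(max(x, 0), w - 1)]

    total = 0.0
    for y in range(h):
        for x in range(w):
            lap = at(y - 1, x) + at(y + 1, x) + at(y, x - 1) + at(y, x + 1) - 4 * at(y, x)
            local = sum(at(y + dy, x + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)) / 9.0
            total += abs(lap) / max(local, 1.0)
    return total if aggregate == "sum" else total / (h * w)


def oracle_hue_peaks(arr, bandwidth=8.0, prominence=0.01, sat_threshold=26.0):
    hist = [0.0] * 360
    for r, g, b in _pixels(arr):
        hue, s, _ = _hsv(r, g, b)
        if s * 255.0 > sat_threshold:
            hist[min(int(hue), 359)] += 1.0
    mass = sum(hist)
    if mass == 0:
        return 0
    # wrapped-Gaussian smoothing, explicit double loop
    norm = sum(
        math.exp(-0.5 * (min(d, 360 - d) / bandwidth) ** 2) for d in range(360)
    )
    smooth = []
    for i in range(360):
        acc = 0.0
        for j in range(360):
            d = abs(i - j)
            d = min(d, 360 - d)
            acc += hist[j] * math.exp(-0.5 * (d / bandwidth) ** 2)
        smooth.append(acc / norm)
    return _count_circular_peaks(smooth, prominence * mass)


def _count_circular_peaks(curve, min_prominence):
    n = len(curve)
    gmax, gmin = max(curve), min(curve)
    count = 0
    for i in range(n):
        h = curve[i]
        if not (h > curve[(i - 1) % n] and h > curve[(i + 1) % n]):
            continue
        if h >= gmax:
            prom = h - gmin
        else:
            sides = []
            for step in (-1, 1):
                low, j = h, i
                while True:
                    j = (j + step) % n
                    if curve[j] > h:
                        break
                    low = min(low, curve[j])
                sides.append(low)
            prom = h - max(sides)
        if prom >= min_prominence:
            count += 1
    return count


def oracle_all_features(arr):
    """All 17 features in one dict, reporting-order keys."""
    out = oracle_channel_stats(arr)
    out["hue_peaks"] = oracle_hue_peaks(arr)
    out["brightness"] = oracle_brightness(arr)
    out["colorfulness"] = oracle_colorfulness(arr)
    out["naturalness"] = oracle_naturalness(arr)
    out["contrast"] = oracle_contrast(arr)
    out["rgb_contrast"] = oracle_rgb_contrast(arr)
    out["sharpness"] = oracle_sharpness(arr)
    return out


def oracle_silhouette(X, labels):
    """Brute-force O(n^2) mean silhouette with Euclidean distance."""
    n = len(X)

    def dist(i, j):
        return math.sqrt(sum((X[i][d] - X[j][d]) ** 2 for d in range(len(X[i]))))

    scores = []
    for i in range(n):
        own = [dist(i, j) for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:  # singleton cluster scores 0 by convention
            scores.append(0.0)
            continue
        a = sum(own) / len(own)
        b = min(
            sum(dist(i, j) for j in range(n) if labels[j] == other)
            / sum(1 for j in range(n) if labels[j] == other)
            for other in set(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return sum(scores) / n


def oracle_permutation_p(a, b, n_perm=100_000, seed=0):
    """Two-sided permutation p-value for the difference in means."""
    import numpy as np

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: a.size].mean() - perm[a.size :].mean()) >= obs:
            hits += 1
    return hits / n_perm
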
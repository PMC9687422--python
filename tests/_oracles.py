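"""Independent brute-force oracles used by the test suite.

Deliberately naive: plain Python loops over the printed formulas, no shared
code with the package implementation.
"""
import math


def shannon_oracle(counts):
    total = sum(counts)
    h = 0.0
    for n in counts:
        if n > 0:
            p = n / total
            h -= p * math.log(p)
    return h


def pielou_oracle(counts):
    s = sum(1 for n in counts if n > 0)
    return shannon_oracle(counts) / math.log(s)


def simpson_oracle(counts):
    total = sum(counts)
    return sum((n / total) ** 2 for n in counts if n > 0)


def _guild_sum(cells, guild):
    return sum(v for (g, _), v in cells.items() if g == guild)


def ncr_oracle(cells):
    ba, fu = _guild_sum(cells, "Ba"), _guild_sum(cells, "Fu")
    return ba / (ba + fu)


def wi_oracle(cells):
    return (_guild_sum(cells, "Ba") + _guild_sum(cells, "Fu")) / _guild_sum(cells, "Pp")


def mi_oracle(cells):
    free = [(cp, v) for (g, cp), v in cells.items() if g in ("Ba", "Fu", "Op")]
    denom = sum(v for _, v in free)
    return sum(cp * v for cp, v in free) / denom


def ppi_oracle(cells, mode="canonical"):
    pp = [(cp, v) for (g, cp), v in cells.items() if g == "Pp"]
    num = sum(cp * v for cp, v in pp)
    if mode == "canonical":
        return num / sum(v for _, v in pp)
    return num / sum(cells.values())


def components_oracle(cells, mode="canonical"):
    c = dict(cells)
    fu2 = c.get(("Fu", 2), 0.0)
    if mode == "canonical":
        b = 0.8 * (c.get(("Ba", 2), 0.0) + fu2)
        e = 3.2 * c.get(("Ba", 1), 0.0) + 0.8 * fu2
    else:
        b = 0.8 * (c.get(("Pp", 2), 0.0) + fu2)
        e = 3.2 * c.get(("Pp", 1), 0.0) + 0.8 * fu2
    weights = {3: 1.8, 4: 3.2, 5: 5.0}
    s = 0.0
    for (g, cp), v in c.items():
        if g in ("Ba", "Fu", "Op") and cp >= 3:
            s += weights[cp] * v
    return b, e, s


def ei_oracle(cells, mode="canonical"):
    b, e, _ = components_oracle(cells, mode)
    return 100.0 * e / (e + b)


def si_oracle(cells, mode="canonical"):
    b, _, s = components_oracle(cells, mode)
    return 100.0 * s / (s + b)


def one_way_ss_oracle(groups):
    """Direct sum-of-squares computation, value by value."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ssb += len(g) * (m - grand) ** 2
        for v in g:
            ssw += (v - m) ** 2
    return ssb, ssw


def two_way_ss_oracle(arr):
    """Direct cell/marginal-mean SS for a balanced a x b x r array."""
    a, b, r = arr.shape
    grand = arr.mean()
    ssa = b * r * sum((arr[i].mean() - grand) ** 2 for i in range(a))
    ssb = a * r * sum((arr[:, j].mean() - grand) ** 2 for j in range(b))
    ssab = 0.0
    sse = 0.0
    for i in range(a):
        for j in range(b):
            cell = arr[i, j].mean()
            ssab += r * (cell - arr[i].mean() - arr[:, j].mean() + grand) ** 2
            for k in range(r):
                sse += (arr[i, j, k] - cell) ** 2
    return ssa, ssb, ssab, sse


def random_tally_cells(rng, max_count=50, ensure=()):
    """Random sparse guild x c-p abundance dict for oracle sweeps."""
    cells = {}
    for g in ("Ba", "Fu", "Pp", "Op"):
        for cp in (1, 2, 3, 4, 5):
            if rng.random() < 0.45:
                v = int(rng.integers(1, max_count))
                if v:
                    cells[(g, cp)] = float(v)
    for key in ensure:
        cells.setdefault(key, float(rng.integers(1, max_count)))
    return cells
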
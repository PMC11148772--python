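"""Independent reference computations used to check the implementation.

These deliberately avoid the library's vectorized code paths: the model
matrix is built one grid point at a time through the public scalar model,
and statistics are computed from their textbook closed forms.
"""
import itertools
import math

import numpy as np

from cetsakit import GridSpec, MeltParams, melt_fraction


def exhaustive_grid_model(grid: GridSpec, temperatures) -> tuple[list, np.ndarray]:
    """Evaluate the melt model at every grid point, one point at a time."""
    temps = np.asarray(temperatures, dtype=float)
    triplets = [MeltParams(m, s, p)
                for m in grid.midpoints()
                for s in grid.slopes()
                for p in grid.plateaus()]
    rows = np.empty((len(triplets), temps.size))
    for i, params in enumerate(triplets):
        rows[i] = melt_fraction(temps, params)
    return triplets, rows


def exhaustive_grid_minimum(curve, grid: GridSpec, model=None):
    """Exact SSE minimum over the full grid, first-occurrence tie-break."""
    if model is None:
        model = exhaustive_grid_model(grid, curve.temperatures)
    triplets, rows = model
    sse = ((rows - curve.fractions[None, :]) ** 2).sum(axis=1)
    i = int(np.argmin(sse))
    return float(sse[i]), triplets[i]


def one_sample_t_pvalue_n3(values):
    """Closed-form two-sided one-sample t p-value for exactly 3 values.

    For df = 2 the t survival function has the elementary form
    sf(t) = (1 - t / sqrt(t^2 + 2)) / 2.
    """
    x = np.asarray(values, dtype=float)
    assert x.size == 3
    t = x.mean() / (x.std(ddof=1) / math.sqrt(3))
    t = abs(t)
    return 1.0 - t / math.sqrt(t * t + 2.0)


def pooled_two_sample_t(a, b):
    """Textbook pooled-variance two-sample t statistic and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def hypergeom_tail_enumeration(k, universe, set_size, n_hits):
    """P(overlap >= k) by exact combinatorial enumeration (small universes)."""
    total = math.comb(universe, n_hits)
    acc = 0
    for overlap in range(k, min(set_size, n_hits) + 1):
        acc += math.comb(set_size, overlap) * math.comb(universe - set_size,
                                                        n_hits - overlap)
    return acc / total
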
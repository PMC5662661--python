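"""Independent oracle routes used by the test suite.

Each oracle deliberately avoids the code path it validates: volumes come
from adaptive quadrature instead of the closed forms, and grouping from
a hand-rolled union-find instead of the graph library.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import wofz

from nmrpeakfit.lineshapes import ShapeParams1D, eval_shape_1d
from nmrpeakfit.peak_fit import ellipses_overlap


def quadrature_volume_1d(p: ShapeParams1D, halfwidth: float = 2000.0) -> float:
    """Adaptive quadrature of the unit-height shape over a wide window.

    ``halfwidth`` is in characteristic widths.  The 1/x^2 tail of
    Lorentzian-type shapes beyond the window is added in closed form so
    the truncation error is far below the comparison tolerance.
    """
    w = p.fwhm if p.fwhm is not None else (p.sigma + p.gamma)
    W = halfwidth * w
    segments = [
        (p.center - W, p.center - 10 * w),
        (p.center - 10 * w, p.center + 10 * w),
        (p.center + 10 * w, p.center + W),
    ]
    val = 0.0
    for a, b in segments:
        v, _ = quad(lambda x: float(eval_shape_1d(p, x)), a, b,
                    limit=400, epsabs=1e-13, epsrel=1e-11)
        val += v

    # closed-form tail integral from W to infinity, both sides
    if p.kind.value == "lorentzian":
        val += 2.0 * p.fwhm**2 / (4.0 * W)
    elif p.kind.value == "galore":
        val += (1.0 - p.mixing_a) * 2.0 * p.fwhm**2 / (4.0 * W)
    elif p.kind.value == "voigt" and p.gamma > 0:
        # unit-height Voigt tail: sigma gamma sqrt2 / (sqrt(pi) Re[w(z0)] x^2)
        apex = wofz(1j * p.gamma / (p.sigma * math.sqrt(2.0))).real
        val += 2.0 * p.sigma * p.gamma * math.sqrt(2.0) / (math.sqrt(math.pi) * apex * W)
    return val


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def brute_force_groups(positions, radii) -> list[list[int]]:
    """All-pairs ellipse test + union-find; returns sorted components."""
    n = len(positions)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if ellipses_overlap(positions[i], radii[i], positions[j], radii[j]):
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    return sorted(sorted(c) for c in comps.values())


def random_peak_config(rng: np.random.Generator, n: int = 50):
    """A crowded random amide-region configuration for grouping tests."""
    positions = np.column_stack([
        rng.uniform(116.5, 119.5, n),
        rng.uniform(8.05, 8.55, n),
    ])
    radii = np.column_stack([
        rng.uniform(0.2, 0.6, n),
        rng.uniform(0.03, 0.08, n),
    ])
    return positions, radii
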
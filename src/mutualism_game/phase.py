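"""Parameter-grid phase diagrams over the (c_t, b_mn) plane.

The plane is partitioned by the two boundary lines ``c_t = b_mn``
(above/right of it: non-mutualist fixation) and ``c_t = b_mn/(n+1)``
(below/left of it: mutualist fixation), with the coexistence wedge in
between.  Increasing neighbourhood size ``n`` rotates the lower line
towards the ``c_t`` axis: the mutualist-fixation region shrinks and the
coexistence wedge widens, while both the non-mutualist region
(``c_t > b_mn``, independent of ``n``) and the "mutualist present"
region (its complement) are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibria import DEFAULT_BOUNDARY_TOL, Regime

__all__ = ["PhaseGrid", "compute_phase_grid", "region_areas", "plot_phase_grid"]


@dataclass(frozen=True)
class PhaseGrid:
    """Regimes and equilibria over a rectangular (c_t, b_mn) grid.

    ``regimes`` and ``x_star`` have shape ``(len(bmn_values),
    len(ct_values))``; ``x_star`` is 0 on non-mutualist-fixation cells,
    1 on mutualist-fixation cells, the interior equilibrium on
    coexistence cells and NaN on degenerate boundaries.
    """

    ct_values: np.ndarray
    bmn_values: np.ndarray
    n: int
    regimes: np.ndarray  # dtype=object of Regime
    x_star: np.ndarray

    def regime_mask(self, label: Regime) -> np.ndarray:
        """Boolean mask of cells carrying ``label``.

        (Direct ``==`` comparison of the object array against a str-enum
        member is unreliable in numpy, which coerces the enum to a
        string array.)
        """
        return np.frompyfunc(lambda r: r is label, 1, 1)(self.regimes).astype(bool)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for i, bmn in enumerate(self.bmn_values):
            for j, ct in enumerate(self.ct_values):
                records.append(
                    {
                        "ct": ct,
                        "bmn": bmn,
                        "n": self.n,
                        "regime": self.regimes[i, j].value,
                        "x_star": self.x_star[i, j],
                    }
                )
        return pd.DataFrame.from_records(records)


def compute_phase_grid(
    ct_range: tuple[float, float],
    bmn_range: tuple[float, float],
    n: int = 1,
    resolution: int = 100,
) -> PhaseGrid:
    """Classify every cell of a rectangular (c_t, b_mn) grid.

    ``resolution`` grid points are placed uniformly (inclusive) along
    each axis; each cell gets its regime label and equilibrium mutualist
    frequency.
    """
    ct_lo, ct_hi = map(float, ct_range)
    bmn_lo, bmn_hi = map(float, bmn_range)
    if not (ct_hi > ct_lo >= 0.0) or not (bmn_hi > bmn_lo >= 0.0):
        raise ValueError(
            f"ranges must be non-degenerate and non-negative, got "
            f"ct_range={ct_range}, bmn_range={bmn_range}"
        )
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")

    ct_values = np.linspace(ct_lo, ct_hi, resolution)
    bmn_values = np.linspace(bmn_lo, bmn_hi, resolution)

    # vectorized regime classification (same inequalities and relative
    # boundary tolerance as classify_regime; asserted cell-by-cell in tests)
    ct_grid, bmn_grid = np.meshgrid(ct_values, bmn_values)
    upper = bmn_grid
    lower = bmn_grid / (n + 1)
    tol = DEFAULT_BOUNDARY_TOL
    scale_up = np.maximum(np.maximum(np.abs(ct_grid), np.abs(upper)), 1e-300)
    scale_lo = np.maximum(np.maximum(np.abs(ct_grid), np.abs(lower)), 1e-300)
    on_boundary = (np.abs(ct_grid - upper) <= tol * scale_up) | (
        np.abs(ct_grid - lower) <= tol * scale_lo
    )
    non_mut = ~on_boundary & (ct_grid > upper)
    mut = ~on_boundary & (ct_grid < lower)
    coex = ~(on_boundary | non_mut | mut)

    regimes = np.empty((resolution, resolution), dtype=object)
    regimes[on_boundary] = Regime.DEGENERATE_BOUNDARY
    regimes[non_mut] = Regime.NON_MUTUALIST_FIXATION
    regimes[mut] = Regime.MUTUALIST_FIXATION
    regimes[coex] = Regime.COEXISTENCE

    x_star = np.full((resolution, resolution), np.nan)
    x_star[non_mut] = 0.0
    x_star[mut] = 1.0
    m = n + 1
    for i, j in zip(*np.nonzero(coex)):
        bmn = bmn_grid[i, j]
        ct = ct_grid[i, j]

        def w_mut(x, bmn=bmn, ct=ct):
            if x == 0.0:
                return bmn - ct
            return bmn * (1.0 - (1.0 - x) ** m) / (x * m) - ct

        x_star[i, j] = brentq(w_mut, 0.0, 1.0, xtol=1e-10)
    return PhaseGrid(
        ct_values=ct_values,
        bmn_values=bmn_values,
        n=n,
        regimes=regimes,
        x_star=x_star,
    )


def region_areas(grid: PhaseGrid) -> dict:
    """Cell counts and fractions per regime label.

    Also reports the derived "mutualist present" region (mutualist
    fixation plus coexistence), used for the region-geometry claims
    about neighbourhood size.
    """
    total = grid.regimes.size
    counts = {label: 0 for label in Regime}
    for label in grid.regimes.ravel():
        counts[label] += 1
    present = counts[Regime.MUTUALIST_FIXATION] + counts[Regime.COEXISTENCE]
    return {
        "counts": {label.value: c for label, c in counts.items()},
        "fractions": {label.value: c / total for label, c in counts.items()},
        "mutualist_present_count": present,
        "mutualist_present_fraction": present / total,
        "total_cells": total,
    }


def plot_phase_grid(grid: PhaseGrid, path: str) -> None:
    """Render the phase diagram to an image file (convenience layer).

    Colours the equilibrium mutualist frequency over the (c_t, b_mn)
    plane and overlays the two analytic boundary lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        grid.ct_values,
        grid.bmn_values,
        grid.x_star,
        cmap="viridis",
        vmin=0.0,
        vmax=1.0,
        shading="nearest",
    )
    fig.colorbar(mesh, ax=ax, label="equilibrium mutualist frequency x*")
    ct = np.asarray(grid.ct_values)
    ax.plot(ct, ct, "w--", lw=1, label=r"$c_t = B_{MN}$")
    ax.plot(ct, ct * (grid.n + 1), "w:", lw=1, label=rf"$c_t = B_{{MN}}/{grid.n + 1}$")
    ax.set_xlim(grid.ct_values[0], grid.ct_values[-1])
    ax.set_ylim(grid.bmn_values[0], grid.bmn_values[-1])
    ax.set_xlabel(r"cost of trade $c_t$")
    ax.set_ylabel(r"benefit of microbial nutrients $B_{MN}$")
    ax.set_title(f"Phase diagram, neighbourhood size n = {grid.n}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
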
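"""Wind-dispersal kernels for raster-based connectivity analysis.

The dispersal of seeds around a mother plant is modelled as a negative
exponential decline with distance: the fraction of seeds deposited at
distance ``x`` metres is proportional to ``(1 - decay)**x``, where
``decay`` is the per-metre decay rate of the kernel.  For use as a focal
(moving) window on a habitat raster, the kernel is discretised onto a
square matrix with an odd number of rows and columns whose centre element
represents the receiving cell.  The centre is set to zero (a cell does not
disperse seeds to itself) and the matrix is normalised to sum to one, so
that a receiving cell entirely surrounded by donor cells would receive the
full seed output of an ideal source (value 1).

The per-metre decay rate is typically derived from a species'
short-distance dispersal range (SDD): the radius within which a stated
quantile (conventionally 95%) of seeds land.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DispersalKernel",
    "decay_from_sdd",
    "kernel_dimension",
    "build_kernel",
    "build_kernel_from_sdd",
    "kernel_from_matrix",
]


@dataclass(frozen=True)
class DispersalKernel:
    """A normalised 2-D seed-fraction matrix with its parameters.

    Attributes
    ----------
    matrix : numpy.ndarray
        Square array of odd dimension ``2 * radius_cells + 1``; each
        element is the fraction of an ideal source's seeds contributed by
        a donor cell at that offset.  The centre element is 0 and the
        matrix sums to 1.
    decay : float or None
        Per-metre decay rate in (0, 1).  ``None`` for user-supplied
        matrices that were not built from an exponential model.
    cell_size : float
        Raster cell size in metres.
    sdd : float or None
        Short-distance dispersal range in metres, recorded when the
        kernel was derived from one.
    """

    matrix: np.ndarray
    decay: float | None
    cell_size: float
    sdd: float | None = None
    isotropic: bool = field(default=True)

    @property
    def radius_cells(self) -> int:
        return self.matrix.shape[0] // 2

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kernel matrix must be square")
        if m.shape[0] % 2 != 1 or m.shape[0] < 3:
            raise ValueError("kernel matrix must have odd dimension >= 3")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "matrix", m)


def decay_from_sdd(
    sdd: float, quantile: float = 0.95, round_digits: int | None = None
) -> float:
    """Per-metre decay rate from a short-distance dispersal range.

    Solves ``(1 - d)**sdd = 1 - quantile`` for ``d``: the rate at which a
    negative exponential kernel must decline so that the stated quantile
    of seeds lands within ``sdd`` metres of the source.

    Parameters
    ----------
    sdd : float
        Short-distance dispersal range in metres (> 0).
    quantile : float
        Fraction of seeds landing within the SDD, in (0, 1).  The field
        convention is 0.95 (occasionally 0.99).
    round_digits : int, optional
        Round the returned rate to this many decimals (presentation
        only; keep full precision for computation).

    Returns
    -------
    float
        Decay rate in (0, 1).

    Examples
    --------
    >>> decay_from_sdd(14, round_digits=2)
    0.19
    >>> decay_from_sdd(30, round_digits=2)
    0.1
    """
    if not sdd > 0:
        raise ValueError(f"sdd must be positive, got {sdd!r}")
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile!r}")
    d = 1.0 - (1.0 - quantile) ** (1.0 / sdd)
    if round_digits is not None:
        d = round(d, round_digits)
    return d


def kernel_dimension(sdd: float, cell_size: float) -> int:
    """Odd matrix dimension covering twice the dispersal range.

    The focal window must extend at least ``sdd`` metres from the centre
    cell in every direction, so the dimension is
    ``2 * ceil(sdd / cell_size) + 1``.

    Examples
    --------
    >>> kernel_dimension(15, 5)
    7
    >>> kernel_dimension(14, 5)
    7
    """
    if not sdd > 0:
        raise ValueError(f"sdd must be positive, got {sdd!r}")
    if not cell_size > 0:
        raise ValueError(f"cell_size must be positive, got {cell_size!r}")
    return 2 * math.ceil(sdd / cell_size) + 1


def _distance_grid(radius_cells: int, cell_size: float) -> np.ndarray:
    offsets = np.arange(-radius_cells, radius_cells + 1, dtype=float)
    dr, dc = np.meshgrid(offsets, offsets, indexing="ij")
    return cell_size * np.hypot(dr, dc)


def build_kernel(decay: float, cell_size: float, radius_cells: int) -> DispersalKernel:
    """Build a normalised negative-exponential dispersal kernel.

    Each element at offset ``(dr, dc)`` from the centre receives the
    unnormalised fraction ``(1 - decay) ** (cell_size * hypot(dr, dc))``,
    the Euclidean distance being measured between cell centres in map
    units.  The centre is zeroed before the matrix is divided by its sum.
    Cells in the matrix corners may lie farther than the nominal dispersal
    range; they keep their exponential value — the matrix boundary is the
    only cutoff.
    """
    if not 0 < decay < 1:
        raise ValueError(f"decay must be in (0, 1), got {decay!r}")
    if not cell_size > 0:
        raise ValueError(f"cell_size must be positive, got {cell_size!r}")
    if radius_cells < 1:
        raise ValueError(f"radius_cells must be >= 1, got {radius_cells!r}")
    dist = _distance_grid(radius_cells, cell_size)
    m = (1.0 - decay) ** dist
    m[radius_cells, radius_cells] = 0.0
    m /= m.sum()
    return DispersalKernel(matrix=m, decay=decay, cell_size=cell_size)


def build_kernel_from_sdd(
    sdd: float, cell_size: float, quantile: float = 0.95
) -> DispersalKernel:
    """Kernel directly from a short-distance dispersal range.

    Convenience composition of :func:`decay_from_sdd`,
    :func:`kernel_dimension` and :func:`build_kernel`; the SDD is
    recorded on the result.  The decay rate is used at full precision.
    """
    decay = decay_from_sdd(sdd, quantile)
    radius = (kernel_dimension(sdd, cell_size) - 1) // 2
    k = build_kernel(decay, cell_size, radius)
    return DispersalKernel(
        matrix=k.matrix, decay=decay, cell_size=cell_size, sdd=sdd
    )


def kernel_from_matrix(
    matrix: np.ndarray,
    cell_size: float,
    decay: float | None = None,
    normalize: bool = True,
) -> DispersalKernel:
    """Wrap a user-supplied kernel matrix (e.g. a wind-biased one).

    Any odd-dimension non-negative square matrix is accepted; the centre
    element is zeroed and, unless ``normalize`` is false, the matrix is
    rescaled to sum to 1.  Isotropy is not assumed for such kernels.  A
    ``decay`` may be supplied if effective distances are to be derived
    from connectivity values later.
    """
    m = np.array(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("kernel matrix elements must be non-negative")
    c = m.shape[0] // 2
    m[c, c] = 0.0
    if normalize:
        s = m.sum()
        if s <= 0:
            raise ValueError("kernel matrix must have a positive sum")
        m /= s
    return DispersalKernel(
        matrix=m, decay=decay, cell_size=cell_size, isotropic=False
    )
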
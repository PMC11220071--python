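"""Raised-cosine basis functions for kernel parametrization.

Kernels (linear filters over time lag, or tuning curves over a variable's
value range) are expressed as weighted sums of half-overlapping raised-cosine
bumps.  With linearly spaced centres and bump half-width equal to the centre
spacing, the bumps form a partition of unity on the whole support, so any
smooth kernel is well approximated with few coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BasisSet", "raised_cosine_basis"]


@dataclass(frozen=True)
class BasisSet:
    """A set of raised-cosine bumps on a discretized domain.

    Parameters
    ----------
    kind : {"event", "tuning"}
        Event bases live on a time-lag grid (seconds relative to the event);
        tuning bases live on a value grid (e.g. cm of position, cm/s of speed).
    centres : array of bump centres, strictly increasing.
    half_width : half-width of each bump; a bump is nonzero on
        ``(centre - half_width, centre + half_width)``.
    domain : the grid on which the basis is evaluated (lag times for event
        kernels, value-bin centres for tuning kernels).
    B : matrix of shape ``(len(domain), n)``; column ``j`` is bump ``j``
        evaluated on the domain.
    """

    kind: str
    support: tuple[float, float]
    centres: np.ndarray
    half_width: float
    domain: np.ndarray
    B: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.B.shape[1]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate all bumps at arbitrary points ``x`` -> (len(x), n)."""
        x = np.asarray(x, dtype=float)
        d = x[:, None] - self.centres[None, :]
        out = 0.5 * (1.0 + np.cos(np.pi * d / self.half_width))
        out[np.abs(d) >= self.half_width] = 0.0
        return out

    def reconstruct(self, weights: np.ndarray) -> np.ndarray:
        """Kernel values on the domain grid for coefficient vector ``weights``."""
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.n,):
            raise ValueError(
                f"expected {self.n} coefficients, got shape {weights.shape}"
            )
        return self.B @ weights

    def project(self, kernel: np.ndarray) -> np.ndarray:
        """Least-squares coefficients reproducing ``kernel`` on the domain."""
        coef, *_ = np.linalg.lstsq(self.B, np.asarray(kernel, float), rcond=None)
        return coef


def raised_cosine_basis(
    n: int,
    support: tuple[float, float],
    kind: str = "event",
    *,
    dx: float | None = None,
    domain: np.ndarray | None = None,
) -> BasisSet:
    """Build ``n`` half-overlapping raised-cosine bumps spanning ``support``.

    Centres are linearly spaced with the first and last at the support edges;
    the bump half-width equals the centre spacing, so neighbouring bumps
    overlap by 50% and the bumps sum to exactly 1 everywhere on the support.

    Parameters
    ----------
    n : number of bumps (>= 1).
    support : ``(lo, hi)`` in seconds (event kernels) or value units
        (tuning kernels).
    dx : grid step used to discretize the domain when ``domain`` is not given.
    domain : explicit evaluation grid (used for tuning bases whose natural
        grid is the sequence of value-bin centres).
    """
    if kind not in ("event", "tuning"):
        raise ValueError(f"unknown basis kind {kind!r}")
    lo, hi = float(support[0]), float(support[1])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError(f"support must be a nonempty finite interval, got {support}")
    if n < 1:
        raise ValueError("n must be >= 1")

    if domain is None:
        if dx is None:
            raise ValueError("either dx or an explicit domain is required")
        n_pts = int(round((hi - lo) / dx))
        if n_pts < 1:
            raise ValueError("support shorter than one grid step")
        domain = lo + np.arange(n_pts) * dx
    else:
        domain = np.asarray(domain, dtype=float)
    if n > domain.size:
        raise ValueError(
            f"{n} bases cannot be represented on a {domain.size}-point grid"
        )

    if n == 1:
        centres = np.array([(lo + hi) / 2.0])
        half_width = (hi - lo) / 2.0
    else:
        centres = np.linspace(lo, hi, n)
        half_width = centres[1] - centres[0]

    basis = BasisSet(
        kind=kind,
        support=(lo, hi),
        centres=centres,
        half_width=half_width,
        domain=domain,
        B=np.empty((0, 0)),
    )
    B = basis.evaluate(domain)
    object.__setattr__(basis, "B", B)
    return basis
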
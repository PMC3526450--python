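"""Restricted cubic spline basis on the log-time scale.

The basis is the one used by flexible parametric (Royston–Parmar) survival
models: ``s(z) = gamma_0 + gamma_1 * z + sum_j gamma_{j+1} * v_j(z)`` where the
``v_j`` are cubic between the boundary knots and constrained to be linear
beyond them.  With no interior knots the basis collapses to ``[1, z]`` and the
survival model reduces to a Weibull on the log-cumulative-hazard scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "rcs_basis_eval", "knots_from_times"]


@dataclass(frozen=True)
class SplineBasis:
    """Knot locations (log-time scale) for a restricted cubic spline.

    ``interior_knots`` may be empty, in which case the basis is linear and the
    implied survival model is Weibull.
    """

    interior_knots: tuple[float, ...] = field(default_factory=tuple)
    boundary_knots: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not hi > lo:
            raise ValueError("boundary knots must satisfy lo < hi")
        ks = tuple(float(k) for k in self.interior_knots)
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("interior knots must be strictly increasing")
        if ks and (ks[0] <= lo or ks[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        object.__setattr__(self, "interior_knots", ks)
        object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def n_interior(self) -> int:
        return len(self.interior_knots)

    @property
    def n_params(self) -> int:
        """Number of spline coefficients: intercept + slope + one per knot."""
        return 2 + self.n_interior

    def to_dict(self) -> dict:
        return {
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(tuple(d["interior_knots"]), tuple(d["boundary_knots"]))


def _cube_pos(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 3


def rcs_basis_eval(z, basis: SplineBasis):
    """Evaluate the restricted cubic basis and its derivative at ``z``.

    Returns ``(B, dB)`` with ``B[..., :] = [1, z, v_1(z), ..., v_K(z)]`` and
    ``dB`` the elementwise derivative with respect to ``z``.  Defined for all
    real ``z``; beyond the boundary knots every ``v_j`` is linear.
    """
    z = np.asarray(z, dtype=float)
    lo, hi = basis.boundary_knots
    K = basis.n_interior
    out = np.empty(z.shape + (2 + K,), dtype=float)
    dout = np.empty_like(out)
    out[..., 0] = 1.0
    dout[..., 0] = 0.0
    out[..., 1] = z
    dout[..., 1] = 1.0
    if K:
        span = hi - lo
        zlo = z - lo
        zhi = z - hi
        c_lo = _cube_pos(zlo)
        c_hi = _cube_pos(zhi)
        d_lo = 3.0 * np.where(zlo > 0.0, zlo, 0.0) ** 2
        d_hi = 3.0 * np.where(zhi > 0.0, zhi, 0.0) ** 2
        for j, kj in enumerate(basis.interior_knots):
            lam = (hi - kj) / span
            zj = z - kj
            out[..., 2 + j] = _cube_pos(zj) - lam * c_lo - (1.0 - lam) * c_hi
            dout[..., 2 + j] = (
                3.0 * np.where(zj > 0.0, zj, 0.0) ** 2 - lam * d_lo - (1.0 - lam) * d_hi
            )
    return out, dout


def knots_from_times(event_times: np.ndarray, n_interior: int) -> SplineBasis:
    """Place knots the Royston–Parmar way.

    Boundary knots at the min/max uncensored log event times; ``n_interior``
    interior knots at equally spaced centiles of the uncensored log times.
    """
    t = np.asarray(event_times, dtype=float)
    t = t[t > 0]
    if t.size < 2:
        raise ValueError("need at least two positive event times to place knots")
    logt = np.log(t)
    lo, hi = float(logt.min()), float(logt.max())
    if not hi > lo:
        # all events at the same time: widen artificially
        lo, hi = lo - 0.5, hi + 0.5
    if n_interior == 0:
        return SplineBasis((), (lo, hi))
    qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    interior = np.quantile(logt, qs)
    # nudge duplicates / boundary collisions apart
    eps = 1e-8 * max(1.0, hi - lo)
    interior = np.clip(interior, lo + eps, hi - eps)
    uniq = []
    for k in interior:
        while uniq and k <= uniq[-1]:
            k = uniq[-1] + eps
        uniq.append(float(k))
    if uniq[-1] >= hi:
        raise ValueError("could not place distinct interior knots")
    return SplineBasis(tuple(uniq), (lo, hi))
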
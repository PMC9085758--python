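"""Concentration-based update modules: diffusion and reaction kinetics.

Every module exposes ``rhs(t, y) -> dc/dt`` over the flat state vector and
is stepped by the shared embedded Euler/midpoint pair, which also derives
each module's local truncation error (see :mod:`mesocell.integrator`).

Rate laws follow mass action: ``v = k * prod(c_substrates)`` for
irreversible nth-order reactions, a forward/backward difference for
reversible pairs, and Michaelis-Menten ``v = kcat*c(E)*c(A)/(km + c(A))``
where an elementary decomposition is not available.  Cross-compartment
reactions (membrane + interior) scale deltas by interface area / volume
factors supplied per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mesocell._kernels import stencil_rhs
from mesocell.state import StateLayout

__all__ = [
    "Module",
    "MassActionReaction",
    "MichaelisMentenReaction",
    "Influx",
    "Diffusion",
    "diffusion_rhs",
    "michaelis_menten_rate",
    "mm_validity_ratio",
    "MMValidityWarning",
]


class MMValidityWarning(UserWarning):
    """Quasi-steady-state assumption of Michaelis-Menten kinetics dubious."""


class Module:
    """Contract for concentration-based modules."""

    name: str = "module"

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _as_index(idx) -> np.ndarray:
    return np.atleast_1d(np.asarray(idx, dtype=int)).ravel()


class MassActionReaction(Module):
    """One elementary irreversible reaction under the law of mass action.

    Parameters
    ----------
    substrates, products:
        lists of (flat_indices, stoichiometry) pairs.  Index arrays must
        be scalars or arrays of one common length n (the reaction is then
        applied elementwise, e.g. per grid point).  Repeated entities are
        expressed through their stoichiometric coefficient.
    k:
        rate constant; units set by the reaction order (s^-1 for first
        order, uM^-1 s^-1 for second order).
    delta_scale:
        optional per-participant multiplier applied to the delta of that
        participant only -- the area/volume conversion at membrane
        interfaces (a reaction consuming a per-area membrane species and
        producing a per-volume interior species scales each side by the
        shared interface geometry).
    rate_scale:
        optional scalar/array multiplying the rate itself, e.g. the area
        fraction of a vesicle's membrane exposed to a grid point.
    """

    def __init__(self, name: str, layout: StateLayout, k: float,
                 substrates, products, delta_scale=None, rate_scale=1.0):
        self.name = name
        self.size = layout.size
        self.k = float(k)
        self.substrates = [(_as_index(i), float(s)) for i, s in substrates]
        self.products = [(_as_index(i), float(s)) for i, s in products]
        n_parts = len(self.substrates) + len(self.products)
        if delta_scale is None:
            delta_scale = [1.0] * n_parts
        self.delta_scale = [np.asarray(f, dtype=float) for f in delta_scale]
        self.rate_scale = rate_scale

    def rate(self, y: np.ndarray) -> np.ndarray:
        v = self.k * np.asarray(self.rate_scale, dtype=float)
        for idx, stoich in self.substrates:
            v = v * y[idx] ** stoich
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.size)
        v = self.rate(y)
        parts = [(idx, -s) for idx, s in self.substrates] + \
                [(idx, +s) for idx, s in self.products]
        for (idx, s), f in zip(parts, self.delta_scale):
            np.add.at(out, idx, s * f * v)
        return out


class MichaelisMentenReaction(Module):
    """Enzymatic conversion A -> P catalyzed by E at v = kcat*E*A/(km+A).

    Checks the quasi-steady-state validity ratio c(E)0/(c(A)0 + km) at
    construction and warns (never raises) when it is not small; the
    threshold is configurable and defaults to 0.1.
    """

    def __init__(self, name: str, layout: StateLayout, kcat: float, km: float,
                 enzyme, substrate, products, rate_scale=1.0,
                 y0: np.ndarray | None = None, validity_threshold: float = 0.1):
        if km <= 0:
            raise ValueError("km must be positive")
        self.name = name
        self.size = layout.size
        self.kcat, self.km = float(kcat), float(km)
        self.enzyme = _as_index(enzyme)
        self.substrate = _as_index(substrate)
        self.products = [(_as_index(i), float(s)) for i, s in products]
        self.rate_scale = rate_scale
        self.validity_flag = False
        if y0 is not None:
            ratio = mm_validity_ratio(np.max(y0[self.enzyme]),
                                      np.min(y0[self.substrate]), km)
            if ratio > validity_threshold:
                self.validity_flag = True
                warnings.warn(
                    f"{name}: quasi-steady-state ratio {ratio:.3g} exceeds "
                    f"{validity_threshold}; Michaelis-Menten treatment dubious",
                    MMValidityWarning, stacklevel=2)

    def rate(self, y: np.ndarray) -> np.ndarray:
        cE, cA = y[self.enzyme], y[self.substrate]
        return self.rate_scale * michaelis_menten_rate(cE, cA, self.kcat, self.km)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.size)
        v = self.rate(y)
        np.add.at(out, self.substrate, -v)
        for idx, s in self.products:
            np.add.at(out, idx, s * v)
        return out


def michaelis_menten_rate(cE, cA, kcat: float, km: float):
    """v = kcat * c(E) * c(A) / (km + c(A)); saturates at kcat*c(E)."""
    return kcat * cE * cA / (km + cA)


def mm_validity_ratio(cE0: float, cA0: float, km: float) -> float:
    """Quasi-steady-state validity diagnostic c(E)0 / (c(A)0 + km)."""
    return float(cE0) / (float(cA0) + float(km))


class Influx(Module):
    """Zeroth-order source: dc/dt = rate(t) at fixed points.

    ``schedule`` is either a constant (uM/s) or a callable t -> rate,
    e.g. the printed stepwise cAMP influx program of the recycling model.
    """

    def __init__(self, name: str, layout: StateLayout, target, schedule):
        self.name = name
        self.size = layout.size
        self.target = _as_index(target)
        self.schedule = schedule if callable(schedule) else (lambda t, r=schedule: r)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.size)
        out[self.target] = self.schedule(t)
        return out


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------

def diffusion_rhs(c: np.ndarray, D: float, ds: float,
                  restriction: np.ndarray,
                  open_h: np.ndarray, open_v: np.ndarray) -> np.ndarray:
    """Five-point stencil with per-neighbor restriction coefficients.

    dc_ij/dt = D/ds^2 * sum_nb r_nb * (c_nb - c_ij) over the four grid
    neighbors, with terms dropped across closed faces (membranes) and the
    domain boundary (zero flux).  A face bordering a fully non-diffusible
    point (r = 0) is closed in both directions, realizing the set of
    non-diffusible points exactly; elsewhere the neighbor's r is applied
    as such, which is asymmetric across interfaces of unequal restriction
    (documented; exact within uniform-restriction regions).
    """
    out = np.zeros_like(c)
    if c.shape[1] > 1:
        both_open = open_h & (restriction[:, :-1] > 0) & (restriction[:, 1:] > 0)
        w = both_open.astype(float)
        d = c[:, 1:] - c[:, :-1]
        out[:, :-1] += w * restriction[:, 1:] * d
        out[:, 1:] -= w * restriction[:, :-1] * d
    if c.shape[0] > 1:
        both_open = open_v & (restriction[:-1, :] > 0) & (restriction[1:, :] > 0)
        w = both_open.astype(float)
        d = c[1:, :] - c[:-1, :]
        out[:-1, :] += w * restriction[1:, :] * d
        out[1:, :] -= w * restriction[:-1, :] * d
    return (D / ds ** 2) * out


class Diffusion(Module):
    """Diffusive transport of one entity field over the simulation grid."""

    def __init__(self, name: str, layout: StateLayout, block: str,
                 D: float, space):
        if D < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        self.name = name
        self.size = layout.size
        self.block = block
        self.sl = layout.slice_of(block)
        self.shape = layout.shape_of(block)
        self.D = float(D)
        self.space = space
        self._refresh_weights()

    def _refresh_weights(self) -> None:
        # face weights are constant for a fixed geometry; cache them
        s = self.space
        r = s.restriction
        live_h = s.open_h & (r[:, :-1] > 0) & (r[:, 1:] > 0)
        live_v = s.open_v & (r[:-1, :] > 0) & (r[1:, :] > 0)
        self._wl = np.ascontiguousarray(live_h * r[:, :-1])  # right cell's view
        self._wr = np.ascontiguousarray(live_h * r[:, 1:])   # left cell's view
        self._wu = np.ascontiguousarray(live_v * r[:-1, :])
        self._wd = np.ascontiguousarray(live_v * r[1:, :])
        self._coef = self.D / s.ds ** 2

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.size)
        c = np.ascontiguousarray(y[self.sl].reshape(self.shape))
        view = out[self.sl].reshape(self.shape)
        stencil_rhs(c, self._wl, self._wr, self._wu, self._wd,
                    self._coef, view)
        return out

    def stable_dt(self) -> float:
        """Forward-Euler positivity bound ds^2 / (4 D) (r <= 1)."""
        return np.inf if self.D == 0 else self.space.ds ** 2 / (4 * self.D)


class ReactionGroup(Module):
    """All mass-action reactions of one compartment family, vectorized.

    Semantically identical to one :class:`MassActionReaction` module per
    reaction -- the controller still sees one local error per reaction --
    but rates, module-local midpoint deltas, and errors are computed in
    closed form over index arrays.  Because every participant of a
    reaction scales the same rate by its stoichiometry, the relative
    local error |D1 - D2| / |D2| of a reaction is the same for all its
    participants and reduces to |v1 - v2| / |v2|.

    Each reaction: (name, k, substrates, products) with substrates /
    products lists of (flat index array or scalar, stoichiometry); at
    most two distinct substrate species per reaction (elementary).  Index
    arrays of length n broadcast the reaction over n grid points.
    """

    is_group = True

    def __init__(self, name: str, layout: StateLayout, reactions,
                 rate_scale=1.0):
        from scipy import sparse
        self.name = name
        self.size = layout.size
        self.rxnames = [r[0] for r in reactions]
        self.n_rx = len(reactions)
        self.worst_name = name
        # per reaction: up to two distinct substrate index columns
        width = max((len(_distinct(r[2])) for r in reactions), default=1)
        if width > 2:
            raise ValueError("elementary reactions have at most 2 substrates")
        n = self.n_rx
        self._k = np.zeros(n)
        self._scale = np.broadcast_to(np.asarray(rate_scale, float), (n,)).copy() \
            if np.ndim(rate_scale) else np.full(n, float(rate_scale))
        self._i1 = np.zeros(n, dtype=int)
        self._e1 = np.zeros(n)
        self._c1 = np.zeros(n)
        self._i2 = np.zeros(n, dtype=int)
        self._e2 = np.zeros(n)
        self._c2 = np.zeros(n)
        self._maxstoich = np.ones(n)
        rows, cols, vals = [], [], []
        for r, (rxname, k, subs, prods) in enumerate(reactions):
            self._k[r] = k
            net: dict[int, float] = {}
            dist = _distinct(subs)
            for col, (idx, e) in enumerate(dist.items()):
                if col == 0:
                    self._i1[r], self._e1[r] = idx, e
                else:
                    self._i2[r], self._e2[r] = idx, e
            for idx, s in subs:
                i = int(np.asarray(idx).ravel()[0])
                net[i] = net.get(i, 0.0) - s
            for idx, s in prods:
                i = int(np.asarray(idx).ravel()[0])
                net[i] = net.get(i, 0.0) + s
            self._maxstoich[r] = max(abs(v) for v in net.values()) if net else 1.0
            self._c1[r] = net.get(int(self._i1[r]), 0.0)
            self._c2[r] = net.get(int(self._i2[r]), 0.0)
            for i, v in net.items():
                if v != 0.0:
                    rows.append(i)
                    cols.append(r)
                    vals.append(v)
        self._S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.size, self.n_rx))

    # -- rate evaluation ---------------------------------------------------
    def rates(self, y: np.ndarray) -> np.ndarray:
        v = self._k * self._scale * y[self._i1] ** self._e1
        m = self._e2 > 0
        if np.any(m):
            v[m] = v[m] * y[self._i2[m]] ** self._e2[m]
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self._S @ self.rates(y)

    # -- grouped embedded step --------------------------------------------
    def group_step(self, t: float, y: np.ndarray, dt: float, floor: float
                   ) -> tuple[np.ndarray, float]:
        """(summed midpoint delta, worst per-reaction log10 error).

        The module-local predictor applies each reaction's own Euler
        delta to its participants before re-evaluating its rate.
        """
        v1 = self.rates(y)
        y1 = y[self._i1] + 0.5 * dt * self._c1 * v1
        y2 = y[self._i2] + 0.5 * dt * self._c2 * v1
        v2 = self._k * self._scale * np.maximum(y1, 0.0) ** self._e1
        m = self._e2 > 0
        if np.any(m):
            v2[m] = v2[m] * np.maximum(y2[m], 0.0) ** self._e2[m]
        live = dt * self._maxstoich * np.maximum(np.abs(v1), np.abs(v2)) > floor
        self.worst_name = self.name
        worst = -np.inf
        if np.any(live):
            diff = np.abs(v1 - v2)[live]
            mag = np.abs(v2)[live]
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(mag > 0, diff / np.where(mag > 0, mag, 1.0),
                               np.inf)
            rel = np.where(diff == 0, 0.0, rel)
            wi = int(np.argmax(rel))
            worst = float(np.log10(rel[wi])) if rel[wi] > 0 else -np.inf
            self.worst_name = f"{self.name}:{self.rxnames[np.nonzero(live)[0][wi]]}"
        return self._S @ (dt * v2), worst


def _distinct(parts) -> dict[int, float]:
    out: dict[int, float] = {}
    for idx, s in parts:
        i = int(np.asarray(idx).ravel()[0])
        out[i] = out.get(i, 0.0) + s
    return out


class CompartmentExchange(Module):
    """First-order equilibration between a well-mixed pool and grid cells.

    Couples a scalar compartment (e.g. the signalosome pool of a storage
    region) to the grid points it overlays: each cell relaxes toward the
    pool concentration at rate k and the pool receives the mean of the
    cell fluxes, which conserves total amount exactly when the pool
    volume equals the summed cell volume.
    """

    def __init__(self, name: str, layout: StateLayout, pool_index,
                 cell_indices, k: float):
        self.name = name
        self.size = layout.size
        self.pool = int(np.asarray(pool_index).ravel()[0])
        self.cells = _as_index(cell_indices)
        self.k = float(k)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.size)
        flux = self.k * (y[self.cells] - y[self.pool])
        out[self.cells] = -flux
        out[self.pool] = float(np.mean(flux))
        return out


class MembraneDiffusion1D(Module):
    """Lateral diffusion of a membrane species along a chain of faces.

    Membrane proteins are laterally mobile (D ~ 0.1 um^2/s); without this
    mobility an endocytotic pit could only ever drain the single face it
    sits on.  The face list is assumed chain-ordered (true for the
    straight membranes built here); ends are zero-flux.
    """

    def __init__(self, name: str, layout: StateLayout, block: str,
                 D: float, ds: float):
        self.name = name
        self.size = layout.size
        self.sl = layout.slice_of(block)
        self.coef = float(D) / float(ds) ** 2

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.size)
        c = y[self.sl]
        acc = np.zeros_like(c)
        d = c[1:] - c[:-1]
        acc[:-1] += d
        acc[1:] -= d
        out[self.sl] = self.coef * acc
        return out
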
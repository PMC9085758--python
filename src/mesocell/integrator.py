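"""Adaptive time stepping with an embedded Euler/midpoint pair.

Each concentration module is advanced with two approximations of the same
step: the first-order Euler delta ``D1 = dt * f(t, c)`` and the
second-order midpoint delta ``D2 = dt * f(t + dt/2, c + D1/2)``.  Their
disagreement yields the local truncation error of the module,

    eps = log10(|D1 - D2| / |D2|),

maximized over all entities and grid points the module touches.  If any
module exceeds the threshold tau_local, the step is halved and retried
(refining the interrupting module first, then rerunning all modules); if
every module's relative error is below theta_local * 10**tau_local the
next step is enlarged.  With tau_local = log10(0.05) no accepted step
carries a local error above 5%, and theta_local = 0.5 sets the
step-increase bound at 2.5%.

After local errors pass, a total-error pass controls the coupling between
modules: the summed delta defines a half-step scaffold state, the deltas
are recomputed there, and the relative deviation between the full-step
and scaffold-based results is held below tau_total.  Because the total
error matters mostly during start-up transients, its evaluation is
skipped while it stays below a negligibility threshold nu (re-armed after
any step increase, or after a fixed number of steps as a backup).

A note on the error formula: the ratio compares the *difference* of the
two approximations to the midpoint delta.  Written as a plain ratio of
deltas the expression cannot express the stated identities (5% error at a
threshold of log10(0.05), divergence mapping to positive values), so the
difference form is used throughout and stated here once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mesocell._kernels import max_rel_error, total_error_rel

__all__ = [
    "ControllerConfig",
    "ErrorController",
    "IntegrationError",
    "midpoint_step",
    "local_error",
    "module_error",
    "observed_order",
    "Simulation",
]


class IntegrationError(RuntimeError):
    """Time step underflow; names the critical module."""


def midpoint_step(y: np.ndarray, rhs, dt: float, t: float = 0.0,
                  predictor: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Return the embedded pair (D1, D2) for one candidate step.

    D1 = dt*f(t, y) is the Euler delta, D2 = dt*f(t + dt/2, y + P/2) the
    midpoint delta; the predictor P defaults to D1 (module-local stepping
    uses the module's own Euler delta).  The accepted update uses D2.
    """
    f1 = np.asarray(rhs(t, y), dtype=float)
    d1 = dt * f1
    p = d1 if predictor is None else predictor
    f2 = np.asarray(rhs(t + dt / 2.0, y + 0.5 * p), dtype=float)
    d2 = dt * f2
    if not math.isfinite(float(d2.sum())):
        raise FloatingPointError("non-finite right-hand side")
    return d1, d2


def local_error(d1: np.ndarray, d2: np.ndarray,
                floor: float = 0.0) -> np.ndarray:
    """Elementwise log10 relative local truncation error.

    Entries where both deltas vanish (or fall below the absolute
    negligibility floor) score -inf (perfect agreement on nothing);
    a vanishing D2 against a non-vanishing D1 scores +inf, forcing a
    step decrease.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    diff = np.abs(d1 - d2)
    mag = np.abs(d2)
    out = np.full(d1.shape, -np.inf)
    negligible = (np.abs(d1) <= floor) & (mag <= floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mag > 0, diff / np.where(mag > 0, mag, 1.0), np.inf)
    ratio = np.where(diff == 0, 0.0, ratio)
    live = ~negligible
    with np.errstate(divide="ignore"):
        out[live] = np.log10(ratio[live])
    return out


def module_error(d1: np.ndarray, d2: np.ndarray, floor: float = 0.0) -> float:
    """Module-level error: max over all entities and grid points.

    Reduction-only fast path of :func:`local_error` (same semantics).
    """
    if d1.size == 0:
        return -np.inf
    r = max_rel_error(np.ascontiguousarray(d1.ravel()),
                      np.ascontiguousarray(d2.ravel()), floor)
    if not math.isfinite(r):
        return np.inf
    return math.log10(r) if r > 0 else -np.inf


def observed_order(coarse, medium, fine) -> float:
    """Convergence-order estimate from solutions at dt, dt/2, dt/4:
    log2 |(c_dt - c_dt/2) / (c_dt/2 - c_dt/4)|."""
    num = np.linalg.norm(np.atleast_1d(coarse - medium))
    den = np.linalg.norm(np.atleast_1d(medium - fine))
    return float(np.log2(num / den))


@dataclass
class ControllerConfig:
    """Tunable parameters of the shared step-size controller.

    tau_local/tau_total are log10 error thresholds (log10(0.05) bounds the
    relative error at 5%); theta_local/theta_total in (0,1) scale the
    step-increase bound in linear space (0.5 -> increase below 2.5%);
    nu is the linear negligibility threshold for total-error skipping
    (default 10**tau_total / 10_000); delta_floor is an absolute delta
    magnitude (uM) below which changes are not error-scored.
    """

    tau_local: float = float(np.log10(0.05))
    theta_local: float = 0.5
    tau_total: float = float(np.log10(0.05))
    theta_total: float = 0.5
    nu: float | None = None
    dt_init: float = 1e-3
    dt_min: float = 1e-12
    dt_max: float = 10.0
    increase_factor: float = 2.0
    decrease_factor: float = 0.5
    backup_interval: int = 100
    increase_cooldown: int = 20
    delta_floor: float = 1e-6
    neg_tol: float = 1e-15
    # displacement control
    d_ref_fraction: float = 0.25      # d_ref = fraction * ds
    theta_disp_plus: float = 0.0      # decrease if log10(|dp|/d_ref) above
    theta_disp_minus: float = -1.0    # allow increase if all below

    def nu_linear(self) -> float:
        return (10.0 ** self.tau_total / 1.0e4) if self.nu is None else self.nu


@dataclass
class ErrorController:
    """Mutable step-size state: current dt, skip state, diagnostics."""

    config: ControllerConfig = field(default_factory=ControllerConfig)
    dt: float = None  # type: ignore[assignment]
    skip_total: bool = False
    steps_since_total: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    steps_since_reject: int = 10 ** 9
    max_accepted_local_rel: float = 0.0
    worst_module: str = ""

    def __post_init__(self):
        if self.dt is None:
            self.dt = self.config.dt_init

    def decrease(self, critical: str = "") -> None:
        self.dt *= self.config.decrease_factor
        self.n_rejected += 1
        self.steps_since_reject = 0
        if self.dt < self.config.dt_min:
            raise IntegrationError(
                f"time step underflow below dt_min={self.config.dt_min}; "
                f"critical module: {critical or 'unknown'}")

    def maybe_increase(self, all_rel_below_bound: bool) -> bool:
        # hysteresis: after a rejection, hold dt for a few steps before
        # trying to grow again (prevents accept/reject thrash at the
        # stability-limited step of stiff modules)
        if all_rel_below_bound and                 self.steps_since_reject >= self.config.increase_cooldown:
            self.dt = min(self.dt * self.config.increase_factor,
                          self.config.dt_max)
            self.skip_total = False  # re-arm total error after an increase
            return True
        return False

    def total_due(self) -> bool:
        if not self.skip_total:
            return True
        return self.steps_since_total >= self.config.backup_interval

    def record_total(self, max_rel: float) -> None:
        self.steps_since_total = 0
        self.skip_total = max_rel < self.config.nu_linear()

    def local_bound(self) -> float:
        return 10.0 ** self.config.tau_local

    def increase_bound(self) -> float:
        # linear-space scaling: theta * 10**tau (0.5 * 5% = 2.5%)
        return self.config.theta_local * 10.0 ** self.config.tau_local


class Simulation:
    """Drives concentration modules (and optionally an agent engine) under
    the shared adaptive-step controller.

    Deterministic: identical initial state and configuration produce the
    identical dt sequence and trajectory (randomness enters only through
    the agent engine's seeded generators).
    """

    def __init__(self, layout, y0: np.ndarray, modules,
                 controller: ErrorController | None = None,
                 agents=None, t0: float = 0.0):
        self.layout = layout
        self.y = np.array(y0, dtype=float)
        self.modules = list(modules)
        self.controller = controller or ErrorController()
        self.agents = agents
        self.t = float(t0)
        self.accepted_local_errors: list[float] = []
        self.step_log: list[tuple[float, float, str, float]] = []

    # -- one attempted step over all modules ------------------------------
    def _one_module(self, m, dt: float, floor: float):
        """(midpoint delta, log10 error) for one module or module group."""
        if getattr(m, "is_group", False):
            return m.group_step(self.t, self.y, dt, floor)
        d1, d2 = midpoint_step(self.y, m.rhs, dt, self.t)
        return d2, module_error(d1, d2, floor)

    def _module_deltas(self, dt: float):
        floor = self.controller.config.delta_floor
        deltas, errors = [], []
        for m in self.modules:
            d2, e = self._one_module(m, dt, floor)
            deltas.append(d2)
            errors.append(e)
        return deltas, errors

    def _module_name(self, idx: int) -> str:
        m = self.modules[idx]
        return getattr(m, "worst_name", m.name)

    def _refine_interrupting(self, idx: int) -> None:
        """The interrupting module keeps requesting decreases until its own
        error passes; all modules are then rerun at the final dt."""
        c = self.controller
        floor = c.config.delta_floor
        while True:
            _, e = self._one_module(self.modules[idx], c.dt, floor)
            if e <= c.config.tau_local:
                return
            c.decrease(self._module_name(idx))

    def step(self) -> float:
        """Advance one accepted step; returns the dt actually taken."""
        c = self.controller
        cfg = c.config
        while True:
            dt = c.dt
            deltas, errors = self._module_deltas(dt)
            worst = int(np.argmax(errors)) if errors else -1
            if errors and errors[worst] > cfg.tau_local:
                c.decrease(self._module_name(worst))
                self._refine_interrupting(worst)
                continue

            if deltas:
                total = deltas[0].copy()
                for d in deltas[1:]:
                    total += d
            else:
                total = np.zeros_like(self.y)
            y_new = self.y + total
            mn = float(y_new.min()) if y_new.size else 0.0
            if mn < 0:
                # negativity is a step-rejection signal, never clamped
                if mn < -cfg.neg_tol:
                    c.decrease("negativity")
                    continue
                np.maximum(y_new, 0.0, out=y_new)  # roundoff dust only

            # agent layer: displacements and chance-rate feasibility
            proposal = None
            if self.agents is not None:
                proposal = self.agents.propose(self.t, dt)
                if proposal.needs_decrease:
                    c.decrease(proposal.reason)
                    continue

            # total-error pass over the summed influence per entity: the
            # scaffold state y + total/2 re-evaluates all modules at the
            # half step; the deviation between the full-step and the
            # scaffold-based results, relative to the resulting
            # concentration, is the total error
            c.steps_since_total += 1
            if self.modules and c.total_due():
                scaffold = self.y + 0.5 * total
                th = self.t + dt / 2.0
                d_scaf = np.asarray(self.modules[0].rhs(th, scaffold),
                                    dtype=float).copy()
                for m in self.modules[1:]:
                    d_scaf += m.rhs(th, scaffold)
                d_scaf *= dt
                max_rel_tot = total_error_rel(total, d_scaf, self.y,
                                              cfg.delta_floor)
                if max_rel_tot > 10.0 ** cfg.tau_total:
                    c.decrease("total-error")
                    continue
                c.record_total(max_rel_tot)
                y_new = self.y + d_scaf
                mn = float(y_new.min()) if y_new.size else 0.0
                if mn < 0:
                    if mn < -cfg.neg_tol:
                        c.decrease("negativity")
                        continue
                    np.maximum(y_new, 0.0, out=y_new)

            # accept
            finite = [e for e in errors if np.isfinite(e)]
            max_rel = max((10.0 ** e for e in finite), default=0.0)
            self.accepted_local_errors.append(max_rel)
            c.max_accepted_local_rel = max(c.max_accepted_local_rel, max_rel)
            if errors:
                c.worst_module = self._module_name(worst)
            self.y = y_new
            if self.agents is not None:
                self.agents.commit(self.t, dt, proposal, self.y)
            self.t += dt
            c.n_accepted += 1
            c.steps_since_reject += 1
            self.step_log.append((self.t, dt, c.worst_module, max_rel))

            all_small = all(
                (not np.isfinite(e)) or (10.0 ** e < c.increase_bound())
                for e in errors)
            if self.agents is not None:
                all_small = all_small and proposal.allows_increase
            c.maybe_increase(all_small)
            return dt

    def run_until(self, t_end: float, observer=None,
                  observe_every: float = 0.0) -> None:
        """Integrate to t_end; optionally call observer(t, y) on a stride."""
        next_obs = self.t
        while self.t < t_end - 1e-12:
            self.controller.dt = min(self.controller.dt, t_end - self.t)
            if observer is not None and self.t >= next_obs:
                observer(self.t, self.y)
                next_obs = self.t + observe_every
            self.step()
        if observer is not None:
            observer(self.t, self.y)
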
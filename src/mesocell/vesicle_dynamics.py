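"""Displacement and qualitative modules for vesicles.

Covers Brownian diffusion of vesicles, molecular-motor transport along
cytoskeletal filaments (with an "actin boost" for freshly scissioned
endocytotic vesicles), stochastic and conditional state changes, the
clathrin-mediated endocytosis pit lifecycle, and SNARE-gated fusion with
membranes.  All randomness flows through named substreams of the run
seed, so the whole agent layer is reproducible bit for bit.

Amount bookkeeping uses uM*um^3 ("amount units"); 1 uM*um^3 corresponds
to ~602 molecules, the factor used to convert SNARE surface densities to
discrete pair counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mesocell.agents import (Filament, VesicleIndex, Vesicle,
                             displacement_decision, face_segment,
                             faces_as_arrays, resolve_displacement)

__all__ = [
    "MOLECULES_PER_AMOUNT",
    "brownian_displacement",
    "filament_advance",
    "cargo_addition_rate",
    "snare_pair_count",
    "StateChangeSpec",
    "EndocytosisParams",
    "EndocytoticPit",
    "EndocytosisManager",
    "FusionParams",
    "FusionManager",
    "MotorSpec",
    "BoostSpec",
    "AgentProposal",
    "VesicleEngine",
]

# molecules per (uM * um^3): 1e-6 mol/L * N_A * 1e-15 L
MOLECULES_PER_AMOUNT = 602.214076


def brownian_displacement(D_v: float, dt: float, xi: np.ndarray) -> np.ndarray:
    """dp = sqrt(2 * D_v * dt) * xi per coordinate, xi ~ N(0, 1).

    The ensemble mean squared displacement over a step is then 4*D_v*dt
    (two dimensions), recovering the configured vesicle diffusivity.
    """
    if D_v < 0:
        raise ValueError("vesicle diffusivity must be non-negative")
    return math.sqrt(2.0 * D_v * dt) * np.asarray(xi, dtype=float)


def filament_advance(fil: Filament, segment: int, position: np.ndarray,
                     distance: float, toward_plus: bool
                     ) -> tuple[np.ndarray, int | None]:
    """Advance `distance` along the filament from `position` on `segment`.

    Walks toward the plus end (ascending vertex order) or minus end,
    rolling over segment vertices; returns (new position, new segment) or
    (position at the end, None) when the filament end is reached, which
    the caller maps to a detach event.
    """
    p = np.asarray(position, dtype=float)
    k = segment
    remaining = float(distance)
    while remaining > 0:
        a, b = fil.points[k], fil.points[k + 1]
        target = b if toward_plus else a
        leg = target - p
        leg_len = float(np.hypot(*leg))
        if leg_len >= remaining:
            return p + leg * (remaining / leg_len), k
        p = target
        remaining -= leg_len
        k = k + 1 if toward_plus else k - 1
        if k < 0 or k >= fil.n_segments:
            return p, None
    return p, k


def cargo_addition_rate(c_cat: float, c_inh: float, k_b: float) -> float:
    """Effective cargo addition rate k_c = c_cat/(c_cat + c_inh) * k_b.

    Bounded by [0, k_b]; monotone in the catalyzing and anti-monotone in
    the inhibiting concentration; 0/0 (no regulator present) maps to 0.
    """
    tot = c_cat + c_inh
    if tot <= 0:
        return 0.0
    return (c_cat / tot) * k_b


def snare_pair_count(density: float, area: float) -> int:
    """Discrete molecule count from a surface density (floored)."""
    return int(math.floor(max(density, 0.0) * area * MOLECULES_PER_AMOUNT))


@dataclass
class StateChangeSpec:
    """One qualitative state-change rule for vesicles.

    condition kinds: 'near_filament' (value: attach distance, um; kind_
    filter via filament_kind), 'near_membrane' (value: distance to the
    named membrane), 'in_region' (value ignored; region name), 'entity_
    threshold' (compartment 'membrane'|'cargo', entity, threshold,
    direction 'above'|'below'), 'chance' (value: frequency f in 1/s,
    fires with p = f*dt; f*dt > 1 requests a smaller step).
    """

    applicable_states: tuple[str, ...]
    new_state: str
    kind: str
    value: float = 0.0
    membrane: str | None = None
    region: str | None = None
    filament_kind: str | None = None
    compartment: str = "cargo"
    entity: str | None = None
    direction: str = "above"


@dataclass
class EndocytosisParams:
    """Pit lifecycle parameters.

    k_p: pit formation rate (1/(s*um^2)); k_b: base cargo addition rate
    (1/s); t_cp: checkpoint deadline (s); c_cp: required cargo surface
    density on the nascent vesicle (uM*um); t_m: maturation time (s);
    cargo_entity: collected species; cat/inh: regulator entity names read
    from the associated membrane face; coat: densities added to the new
    vesicle's membrane; vesicle_radius (um).
    """

    k_p: float
    k_b: float
    t_cp: float
    c_cp: float
    t_m: float
    cargo_entity: str = "AQP2"
    catalyzing: str | None = None
    inhibiting: str | None = None
    coat: dict[str, float] = field(default_factory=dict)
    vesicle_radius: float = 0.05


@dataclass
class EndocytoticPit:
    """Sphere-like precursor of a clathrin-coated vesicle on a membrane face."""

    id: int
    face_index: int
    birth: float
    phase: str = "collecting"        # collecting | maturing | aborted | scissioned
    checkpoint_time: float | None = None
    cargo: dict[str, float] = field(default_factory=dict)   # amounts, uM*um^3


@dataclass
class PitEvent:
    t: float
    kind: str            # spawn | abort | checkpoint | scission
    pit_id: int
    lifetime: float = 0.0


class EndocytosisManager:
    """Pit lifecycle on one membrane: spawn, collect, checkpoint, mature.

    Pits spawn as a Poisson process at rate k_p times the membrane area;
    each collecting pit absorbs cargo from its face at the regulated rate
    of the catalyzing/inhibiting balance, never more than is present.  A
    pit that misses the required density before its deadline aborts and
    returns every collected molecule to its face; one that passes matures
    for t_m and scissions into a coated vesicle.
    """

    def __init__(self, membrane, params: EndocytosisParams, rng,
                 space=None, regulator_conc=None):
        self.membrane = membrane
        self.p = params
        self.rng = rng
        self.space = space
        # optional override: () -> (c_cat, c_inh) from a shared pool
        # (kinase cascade integrated elsewhere) instead of per-face species
        self.regulator_conc = regulator_conc
        self.pits: list[EndocytoticPit] = []
        self.events: list[PitEvent] = []
        self.lifetimes_abortive: list[float] = []
        self.lifetimes_productive: list[float] = []
        self.n_spawned = 0
        self._next_id = 0

    @property
    def vesicle_area(self) -> float:
        return 4.0 * math.pi * self.p.vesicle_radius ** 2

    def pit_density(self, pit: EndocytoticPit) -> float:
        return pit.cargo.get(self.p.cargo_entity, 0.0) / self.vesicle_area

    def _face_conc(self, face_index: int, entity: str | None) -> float:
        if entity is None:
            return 0.0
        arr = self.membrane.conc(entity)
        return 0.0 if arr is None else float(arr[face_index])

    def step(self, t: float, dt: float) -> list[Vesicle]:
        """Advance all pits by one accepted step; returns new vesicles."""
        new_vesicles: list[Vesicle] = []
        area = self.membrane.total_area
        face_area = self.membrane.face_area
        # spawn
        n_new = self.rng.poisson(self.p.k_p * area * dt)
        for _ in range(n_new):
            face = int(self.rng.integers(0, self.membrane.n_faces))
            pit = EndocytoticPit(self._next_id, face, birth=t)
            self._next_id += 1
            self.n_spawned += 1
            self.pits.append(pit)
            self.events.append(PitEvent(t, "spawn", pit.id))
        survivors: list[EndocytoticPit] = []
        for pit in self.pits:
            if pit.phase == "collecting":
                cav = self.membrane.conc(self.p.cargo_entity)
                if cav is not None:
                    if self.regulator_conc is not None:
                        c_cat, c_inh = self.regulator_conc()
                        k_c = cargo_addition_rate(c_cat, c_inh, self.p.k_b)
                    elif self.p.catalyzing is None and \
                            self.p.inhibiting is None:
                        k_c = self.p.k_b          # unregulated collection
                    else:
                        c_cat = self._face_conc(pit.face_index, self.p.catalyzing)
                        c_inh = self._face_conc(pit.face_index, self.p.inhibiting)
                        k_c = cargo_addition_rate(c_cat, c_inh, self.p.k_b)
                    want = k_c * float(cav[pit.face_index]) * dt
                    take = min(want, float(cav[pit.face_index]))
                    cav[pit.face_index] -= take
                    pit.cargo[self.p.cargo_entity] = \
                        pit.cargo.get(self.p.cargo_entity, 0.0) + take * face_area
                if self.pit_density(pit) >= self.p.c_cp:
                    pit.phase = "maturing"
                    pit.checkpoint_time = t + dt
                    self.events.append(PitEvent(t + dt, "checkpoint", pit.id))
                    survivors.append(pit)
                elif (t + dt) - pit.birth >= self.p.t_cp:
                    # abort: all collected cargo returns to the face
                    pit.phase = "aborted"
                    for ent, amount in pit.cargo.items():
                        arr = self.membrane.ensure(ent)
                        arr[pit.face_index] += amount / face_area
                    life = (t + dt) - pit.birth
                    self.lifetimes_abortive.append(life)
                    self.events.append(PitEvent(t + dt, "abort", pit.id, life))
                else:
                    survivors.append(pit)
            elif pit.phase == "maturing":
                if (t + dt) - pit.checkpoint_time >= self.p.t_m:
                    pit.phase = "scissioned"
                    life = (t + dt) - pit.birth
                    self.lifetimes_productive.append(life)
                    self.events.append(PitEvent(t + dt, "scission", pit.id, life))
                    new_vesicles.append(self._scission(pit, t + dt))
                else:
                    survivors.append(pit)
        self.pits = survivors
        return new_vesicles

    def _scission(self, pit: EndocytoticPit, t: float) -> Vesicle:
        (i, j), (i2, j2) = self.membrane.faces[pit.face_index]
        a, b = face_segment(self.membrane.faces[pit.face_index],
                            self.membrane.ds)
        center = (a + b) / 2.0
        # spawn on the interior side of the face, offset by the radius
        normal = self._face_normal(pit.face_index)
        pos = center + normal * (self.p.vesicle_radius * 1.5)
        membrane_conc = {ent: amount / self.vesicle_area
                         for ent, amount in pit.cargo.items()}
        for ent, dens in self.p.coat.items():
            membrane_conc[ent] = membrane_conc.get(ent, 0.0) + dens
        v = Vesicle(id=-1, position=pos, radius=self.p.vesicle_radius,
                    state="scissioned", membrane=membrane_conc,
                    birth_time=t)
        v.spawn_normal = normal  # direction of the actin boost
        return v

    def _face_normal(self, face_index: int) -> np.ndarray:
        """Unit normal pointing from the face into the simulation interior
        (away from the nearest domain edge)."""
        (i, j), (i2, j2) = self.membrane.faces[face_index]
        if self.space is None:
            return np.array([0.0, 1.0])
        if (i2, j2) == (i + 1, j):   # horizontal wall; normal is +/- y
            up = i < self.space.n_rows / 2
            return np.array([0.0, 1.0]) if up else np.array([0.0, -1.0])
        left = j < self.space.n_cols / 2
        return np.array([1.0, 0.0]) if left else np.array([-1.0, 0.0])

    def counts(self) -> tuple[int, int]:
        return (len(self.lifetimes_productive), len(self.lifetimes_abortive))


@dataclass
class FusionParams:
    """SNARE-gated fusion: duration t_f (s), attachment distance d_a (um),
    Q/R-SNARE entity names, minimal pair count n_p."""

    t_f: float
    d_a: float
    snare_q: str = "QSNARE"
    snare_r: str = "RSNARE"
    n_p: int = 3


class FusionManager:
    """Initiates and completes vesicle fusion with a target membrane.

    A vesicle whose surface comes within d_a of a membrane face starts
    fusing if at least n_p Q/R-SNARE pairs can be formed from the target
    patch and the vesicle membrane; after t_f the vesicle's membrane
    species merge into the target face (area-scaled), its cargo merges
    into the interior compartment of the face's grid point, and the
    vesicle is removed.  Amounts are conserved exactly.
    """

    def __init__(self, membrane, params: FusionParams, space, layout=None,
                 grid_block: dict[str, str] | None = None,
                 eligible_states=("unattached", "tethered")):
        self.membrane = membrane
        self.p = params
        self.space = space
        self.layout = layout
        self.grid_block = grid_block or {}
        self.eligible_states = tuple(eligible_states)
        self.active: dict[int, tuple[float, int]] = {}   # vid -> (start, face)
        self.completed: list[tuple[float, int]] = []

    def _nearest_face(self, v: Vesicle) -> tuple[int, float]:
        best, bd = -1, np.inf
        for k, face in enumerate(self.membrane.faces):
            a, b = face_segment(face, self.membrane.ds)
            ab = b - a
            tt = np.clip(np.dot(v.position - a, ab) / np.dot(ab, ab), 0, 1)
            d = float(np.hypot(*(v.position - (a + tt * ab)))) - v.radius
            if d < bd:
                best, bd = k, d
        return best, bd

    def try_initiate(self, v: Vesicle, t: float) -> bool:
        if v.id in self.active or v.state == "fusing":
            return False
        k, d = self._nearest_face(v)
        if k < 0 or d > self.p.d_a:
            return False
        q_dens = self.membrane.conc(self.p.snare_q)
        q_count = 0 if q_dens is None else snare_pair_count(
            float(q_dens[k]), self.membrane.face_area)
        r_count = snare_pair_count(v.membrane.get(self.p.snare_r, 0.0),
                                   v.surface_area)
        if min(q_count, r_count) < self.p.n_p:
            return False
        v.state = "fusing"
        self.active[v.id] = (t, k)
        return True

    def step(self, t: float, dt: float, vesicles: dict[int, Vesicle],
             y: np.ndarray | None = None) -> list[int]:
        """Complete due fusions; returns ids of removed vesicles."""
        removed = []
        for vid, (t0, k) in list(self.active.items()):
            if (t + dt) - t0 < self.p.t_f:
                continue
            v = vesicles[vid]
            # membrane species -> target face (per-area density, scaled)
            for ent, dens in v.membrane.items():
                arr = self.membrane.ensure(ent)
                arr[k] += dens * v.surface_area / self.membrane.face_area
            # cargo -> interior compartment of the face's cis-side point
            if y is not None and v.cargo:
                (i, j), _ = self.membrane.faces[k]
                for ent, conc in v.cargo.items():
                    block = self.grid_block.get(ent)
                    if block is None:
                        continue
                    fld = self.layout.view(y, block)
                    fld[i, j] += conc * v.volume / self.space.point_volume
            del self.active[vid]
            removed.append(vid)
            self.completed.append((t + dt, vid))
        return removed


@dataclass
class MotorSpec:
    """Motor transport on one filament kind: speed v_m (um/s), walking
    direction, states it applies to, and the state after detaching."""

    filament_kind: str
    v_m: float
    toward_plus: bool = True
    applicable_states: tuple[str, ...] = ("actin_attached",)
    detach_state: str = "unattached"


@dataclass
class BoostSpec:
    """Directed unguided boost orthogonal to the spawning membrane:
    v = v_b * c(scaling entity in the coat), applied in given states."""

    v_b: float
    scaling_entity: str = "clathrin"
    applicable_states: tuple[str, ...] = ("scissioned",)
    duration: float = 1.0


@dataclass
class AgentProposal:
    needs_decrease: bool = False
    reason: str = ""
    allows_increase: bool = True
    displacements: dict[int, np.ndarray] = field(default_factory=dict)
    filament_moves: dict[int, tuple[np.ndarray, int | None]] = field(
        default_factory=dict)


class VesicleEngine:
    """The agent layer: owns vesicles, filaments, pits, and fusion sites,
    and plugs into the integrator's propose/commit step contract.

    propose() computes every displacement for the candidate step and
    reports whether the step must shrink (displacement bound exceeded, or
    a chance-rule probability f*dt > 1) or may grow.  commit() applies
    displacements under the discard collision policy, re-indexes vesicles
    onto the grid, runs state changes, the pit lifecycle, and fusion.
    """

    def __init__(self, space, controller_config, seed: int,
                 brownian_D: float = 0.0,
                 brownian_states: tuple[str, ...] = ("unattached",),
                 motors: list[MotorSpec] = (),
                 boost: BoostSpec | None = None,
                 state_changes: list[StateChangeSpec] = (),
                 endocytosis: EndocytosisManager | None = None,
                 fusion: FusionManager | None = None,
                 barriers=()):
        self.space = space
        self.cfg = controller_config
        self.vesicles: dict[int, Vesicle] = {}
        self.filaments: list[Filament] = []
        self.motors = list(motors)
        self.boost = boost
        self.brownian_D = brownian_D
        self.brownian_states = tuple(brownian_states)
        self.state_changes = list(state_changes)
        self.endocytosis = endocytosis
        self.fusion = fusion
        self.barriers = tuple(barriers)
        ss = np.random.SeedSequence([int(seed) % (2 ** 31), 77])
        kids = ss.spawn(3)
        self.rng_brownian = np.random.default_rng(kids[0])
        self.rng_chance = np.random.default_rng(kids[1])
        self.rng_pits = np.random.default_rng(kids[2])
        self.index = VesicleIndex(space.ds, space.n_rows, space.n_cols)
        self._next_id = 0
        self._closed_faces = space.membrane_faces()
        self._face_arrays = faces_as_arrays(self._closed_faces, space.ds)
        self._ordered_cache = None
        self.trajectory: list[tuple[float, int, str, float, float]] = []
        self.trajectory_stride = 25     # record every Nth accepted step
        self._commit_count = 0
        # optional model-specific qualitative hook run each accepted step
        self.custom_step = None

    # -- population management -------------------------------------------
    def add_vesicle(self, v: Vesicle) -> Vesicle:
        if v.id < 0:
            v.id = self._next_id
        self._next_id = max(self._next_id, v.id + 1)
        self.vesicles[v.id] = v
        self._ordered_cache = None
        self.index.rebuild(self._ordered())
        return v

    def _ordered(self) -> list[Vesicle]:
        if self._ordered_cache is None:
            self._ordered_cache = [self.vesicles[k]
                                   for k in sorted(self.vesicles)]
        return self._ordered_cache

    # -- integrator contract ----------------------------------------------
    def propose(self, t: float, dt: float) -> AgentProposal:
        prop = AgentProposal()
        max_chance = max((s.value for s in self.state_changes
                          if s.kind == "chance"), default=0.0)
        if max_chance * dt > 1.0:
            prop.needs_decrease = True
            prop.reason = "chance-frequency"
            return prop
        d_ref = self.cfg.d_ref_fraction * self.space.ds
        for v in self._ordered():
            dp = np.zeros(2)
            if v.state in self.brownian_states and self.brownian_D > 0:
                xi = self.rng_brownian.standard_normal(2)
                dp += brownian_displacement(self.brownian_D, dt, xi)
            for m in self.motors:
                if v.state in m.applicable_states and v.filament is not None:
                    newp, seg = filament_advance(
                        v.filament, v.segment, v.position, m.v_m * dt,
                        m.toward_plus)
                    prop.filament_moves[v.id] = (newp, seg)
                    dp += newp - v.position
            if (self.boost is not None and v.state in
                    self.boost.applicable_states and
                    hasattr(v, "spawn_normal")):
                c_s = v.membrane.get(self.boost.scaling_entity, 0.0)
                dp += self.boost.v_b * c_s * dt * v.spawn_normal
            prop.displacements[v.id] = dp
        decision = displacement_decision(
            prop.displacements.values(), d_ref,
            self.cfg.theta_disp_plus, self.cfg.theta_disp_minus)
        if decision == "decrease":
            prop.needs_decrease = True
            prop.reason = "displacement"
        prop.allows_increase = decision == "increase"
        return prop

    def commit(self, t: float, dt: float, prop: AgentProposal,
               y: np.ndarray | None = None) -> None:
        # displacements, deterministic id order, discard policy
        for v in self._ordered():
            dp = prop.displacements.get(v.id)
            if dp is None or not np.any(dp):
                continue
            accepted = resolve_displacement(
                v, v.position + dp, self.space, self.index,
                self._closed_faces, self.barriers,
                face_arrays=self._face_arrays)
            moved = not np.array_equal(accepted, v.position)
            v.position = accepted
            if moved and v.id in prop.filament_moves:
                _, seg = prop.filament_moves[v.id]
                if seg is None:      # reached the filament end: detach
                    for m in self.motors:
                        if v.state in m.applicable_states:
                            v.state = m.detach_state
                    v.filament, v.segment = None, None
                else:
                    v.segment = seg
        self.index.rebuild(self._ordered())
        if self.custom_step is not None:
            self.custom_step(self, t, dt, y)
        self._apply_state_changes(t, dt)
        if self.endocytosis is not None:
            for v in self.endocytosis.step(t, dt):
                self.add_vesicle(v)
        if self.fusion is not None:
            for v in self._ordered():
                if v.state in self.fusion.eligible_states:
                    self.fusion.try_initiate(v, t + dt)
            removed = self.fusion.step(t, dt, self.vesicles, y)
            for vid in removed:
                del self.vesicles[vid]
            if removed:
                self._ordered_cache = None
                self.index.rebuild(self._ordered())
        self._commit_count += 1
        if self._commit_count % self.trajectory_stride == 0:
            for v in self._ordered():
                self.trajectory.append((t + dt, v.id, v.state,
                                        float(v.position[0]),
                                        float(v.position[1])))

    # -- qualitative state changes -----------------------------------------
    def _apply_state_changes(self, t: float, dt: float) -> None:
        for v in self._ordered():
            for spec in self.state_changes:
                if v.state not in spec.applicable_states:
                    continue
                if self._condition_met(v, spec, dt):
                    v.state = spec.new_state
                    if spec.kind == "near_filament":
                        fil, seg = self._nearest_filament(v, spec)
                        v.filament, v.segment = fil, seg
                    if spec.kind == "chance" and v.filament is not None:
                        v.filament, v.segment = None, None
                    break

    def _nearest_filament(self, v: Vesicle, spec: StateChangeSpec):
        best = (None, None, np.inf)
        for f in self.filaments:
            if spec.filament_kind and f.kind != spec.filament_kind:
                continue
            seg, d, _ = f.nearest(v.position)
            if d < best[2]:
                best = (f, seg, d)
        return best[0], best[1]

    def _condition_met(self, v: Vesicle, spec: StateChangeSpec,
                       dt: float) -> bool:
        if spec.kind == "near_filament":
            _, seg, d = self._nearest_filament_dist(v, spec)
            return d - v.radius <= spec.value
        if spec.kind == "near_membrane":
            mem = self.space.membranes.get(spec.membrane)
            if mem is None:
                return False
            dmin = np.inf
            for face in mem.faces:
                a, b = face_segment(face, self.space.ds)
                ab = b - a
                tt = np.clip(np.dot(v.position - a, ab) / np.dot(ab, ab), 0, 1)
                dmin = min(dmin, float(np.hypot(*(v.position - (a + tt * ab)))))
            return dmin - v.radius <= spec.value
        if spec.kind == "in_region":
            for reg in self.barriers:
                if reg.name == spec.region:
                    return reg.contains(v.position)
            return False
        if spec.kind == "entity_threshold":
            pool = v.membrane if spec.compartment == "membrane" else v.cargo
            c = pool.get(spec.entity, 0.0)
            return c >= spec.value if spec.direction == "above" else c < spec.value
        if spec.kind == "chance":
            return bool(self.rng_chance.random() < spec.value * dt)
        raise ValueError(f"unknown state-change condition {spec.kind!r}")

    def _nearest_filament_dist(self, v: Vesicle, spec: StateChangeSpec):
        best = (None, None, np.inf)
        for f in self.filaments:
            if spec.filament_kind and f.kind != spec.filament_kind:
                continue
            seg, d, _ = f.nearest(v.position)
            if d < best[2]:
                best = (f, seg, d)
        return best
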
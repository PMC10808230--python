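"""Overdamped agent-based dynamics of actin filaments, crosslinkers and motors.

Filaments are bead-spring chains (harmonic stretching between consecutive
beads, harmonic discrete-Laplacian bending) on a square periodic domain.
Connectors are transient harmonic springs between points on two distinct
filaments; motors are connectors whose attachment arc-length coordinates walk
toward the barbed end (bead index increasing) at constant speed.  Integration
is Euler--Maruyama with a diagonal drag tensor: displacement components are
force / gamma_x (longitudinal) and force / gamma_y (circumferential), so
``gamma_y > gamma_x`` slows circumferential motion and encodes anisotropic
membrane friction.

Filament turnover removes a whole filament (releasing its connectors) and
re-inserts it straight at a uniform random position/orientation, conserving
the filament count; this is the effective-diffusion mechanism that limits
cluster coarsening and sets the pattern interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .params import SimulationParams, ConditionPreset

KIND_CROSSLINKER = 0
KIND_MOTOR = 1


@dataclass
class Connectors:
    """Bound connector springs as parallel arrays (edge list)."""

    kind: np.ndarray      # int8, KIND_CROSSLINKER | KIND_MOTOR
    fil_a: np.ndarray     # int32 filament index
    fil_b: np.ndarray
    s_a: np.ndarray       # float64 arc-length coordinate (µm) along filament
    s_b: np.ndarray
    age: np.ndarray       # float64, s since binding

    @classmethod
    def empty(cls) -> "Connectors":
        return cls(*(np.empty(0, dt) for dt in
                     (np.int8, np.int32, np.int32, float, float, float)))

    def __len__(self) -> int:
        return len(self.kind)

    def select(self, keep: np.ndarray) -> "Connectors":
        return Connectors(self.kind[keep], self.fil_a[keep], self.fil_b[keep],
                          self.s_a[keep], self.s_b[keep], self.age[keep])

    def extend(self, other: "Connectors") -> "Connectors":
        return Connectors(
            *(np.concatenate([a, b]) for a, b in
              zip((self.kind, self.fil_a, self.fil_b,
                   self.s_a, self.s_b, self.age),
                  (other.kind, other.fil_a, other.fil_b,
                   other.s_a, other.s_b, other.age))))

    def count(self, kind: int) -> int:
        return int(np.sum(self.kind == kind))


@dataclass
class SimulationState:
    """The simulator's evolving world: bead positions plus bound connectors."""

    params: SimulationParams
    positions: np.ndarray          # (n_filaments, beads_per_filament, 2), µm
    connectors: Connectors
    time: float
    rng: np.random.Generator

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0] * self.positions.shape[1]

    def bead_coords(self) -> np.ndarray:
        """All bead positions flattened to (n_beads, 2)."""
        return self.positions.reshape(-1, 2)


@dataclass
class Trajectory:
    """Snapshots of a run at a fixed stride."""

    params: SimulationParams
    times: list[float] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    connector_counts: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)

    def append(self, state: SimulationState) -> None:
        self.times.append(state.time)
        self.positions.append(state.positions.copy())
        self.connector_counts.append(
            (state.connectors.count(KIND_CROSSLINKER),
             state.connectors.count(KIND_MOTOR)))


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image displacement on the periodic square domain."""
    return d - box * np.round(d / box)


def init_state(params: SimulationParams) -> SimulationState:
    """Place straight filaments uniformly at random; no connectors bound.

    Raises ``ValueError`` when the requested filament density is implausible
    (total contour length at an effective 10 nm width exceeding the box area),
    which signals a misconfiguration rather than a physical regime.
    """
    total_contour = params.n_filaments * params.filament_length
    if total_contour * 0.01 > params.box_size ** 2:
        raise ValueError(
            f"filament density too high: {params.n_filaments} filaments of "
            f"length {params.filament_length:.3f} µm cannot plausibly fit a "
            f"{params.box_size} µm box")
    rng = np.random.default_rng(params.seed)
    F, B = params.n_filaments, params.beads_per_filament
    centers = rng.uniform(0.0, params.box_size, size=(F, 2))
    theta = rng.uniform(0.0, 2 * np.pi, size=F)
    tangent = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    offsets = (np.arange(B) - (B - 1) / 2.0) * params.bead_spacing
    pos = centers[:, None, :] + offsets[None, :, None] * tangent[:, None, :]
    pos %= params.box_size
    return SimulationState(params, pos, Connectors.empty(), 0.0, rng)


def _attachment_points(state: SimulationState, fil: np.ndarray,
                       s: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """Interpolated connector attachment positions.

    Returns (points, bead index i, weight w) with the attachment between
    beads i and i+1 at fraction w, using minimum-image segment vectors so
    interpolation is wrap-safe.
    """
    p = state.params
    ds = p.bead_spacing
    i = np.clip((s / ds).astype(int), 0, p.beads_per_filament - 2)
    w = s / ds - i
    a = state.positions[fil, i]
    b = state.positions[fil, i + 1]
    pts = a + w[:, None] * _min_image(b - a, p.box_size)
    return pts, i, w


def _internal_forces(state: SimulationState) -> np.ndarray:
    """Stretch + bend forces per bead, shape (F, B, 2)."""
    p = state.params
    pos = state.positions
    box = p.box_size
    seg = _min_image(pos[:, 1:] - pos[:, :-1], box)       # (F, B-1, 2)
    length = np.linalg.norm(seg, axis=-1)
    unit = seg / np.maximum(length, 1e-12)[..., None]
    tension = p.k_stretch * (length - p.bead_spacing)     # (F, B-1)
    f_seg = tension[..., None] * unit
    forces = np.zeros_like(pos)
    forces[:, :-1] += f_seg
    forces[:, 1:] -= f_seg
    if p.beads_per_filament >= 3 and p.k_bend > 0:
        # E = (k/2) sum_i |seg_i - seg_{i-1}|^2, a discrete-Laplacian penalty
        b = seg[:, 1:] - seg[:, :-1]                      # (F, B-2, 2)
        forces[:, :-2] -= p.k_bend * b
        forces[:, 1:-1] += 2 * p.k_bend * b
        forces[:, 2:] -= p.k_bend * b
    return forces


def _connector_forces(state: SimulationState) -> np.ndarray:
    p = state.params
    con = state.connectors
    forces = np.zeros_like(state.positions)
    if len(con) == 0:
        return forces
    pa, ia, wa = _attachment_points(state, con.fil_a, con.s_a)
    pb, ib, wb = _attachment_points(state, con.fil_b, con.s_b)
    d = _min_image(pb - pa, p.box_size)
    dist = np.linalg.norm(d, axis=-1)
    unit = d / np.maximum(dist, 1e-12)[:, None]
    rest = np.where(con.kind == KIND_MOTOR, p.motor_rest_length,
                    p.connector_rest_length)
    f = p.k_connector * (dist - rest)[:, None] * unit
    B = p.beads_per_filament
    flat = forces.reshape(-1, 2)
    for fil, i, w, sign in ((con.fil_a, ia, wa, +1.0),
                            (con.fil_b, ib, wb, -1.0)):
        idx0 = fil * B + i
        for comp in range(2):
            np.add.at(flat[:, comp], idx0, sign * (1 - w) * f[:, comp])
            np.add.at(flat[:, comp], idx0 + 1, sign * w * f[:, comp])
    return forces


def step(state: SimulationState) -> SimulationState:
    """One Euler--Maruyama update; mutates and returns ``state``.

    Raises ``RuntimeError`` when any bead moves farther than one bead spacing
    in a single step, which indicates the time step is too large for the
    chosen stiffnesses.
    """
    p = state.params
    forces = _internal_forces(state) + _connector_forces(state)
    gamma = np.array([p.gamma_x, p.gamma_y])
    disp = forces * (p.dt / gamma)
    if p.temperature_noise > 0:
        sigma = np.sqrt(2.0 * p.temperature_noise * p.dt / gamma)
        disp = disp + state.rng.standard_normal(disp.shape) * sigma
    max_disp = float(np.max(np.abs(disp))) if disp.size else 0.0
    if max_disp > p.bead_spacing:
        raise RuntimeError(
            f"unstable step at t={state.time:.4f}s: max bead displacement "
            f"{max_disp:.4g} µm exceeds bead spacing {p.bead_spacing} µm; "
            f"reduce dt or stiffnesses")
    state.positions = (state.positions + disp) % p.box_size
    # motors walk toward the barbed end (arc length increasing); whether a
    # motor detaches at the end or dwells there is a model switch
    con = state.connectors
    if len(con):
        motor = con.kind == KIND_MOTOR
        if motor.any():
            adv = p.motor_speed * p.dt
            con.s_a[motor] += adv
            con.s_b[motor] += adv
            L = p.filament_length
            if p.motor_end_dwell:
                con.s_a[motor] = np.minimum(con.s_a[motor], L)
                con.s_b[motor] = np.minimum(con.s_b[motor], L)
            else:
                off_end = motor & ((con.s_a > L) | (con.s_b > L))
                if off_end.any():
                    state.connectors = con.select(~off_end)
        state.connectors.age += p.dt
    state.time += p.dt
    return state


def update_connectors(state: SimulationState, dt: float | None = None
                      ) -> SimulationState:
    """Stochastic connector unbinding and binding over an interval ``dt``.

    Unbinding is a Poisson process with kind-specific rates (crosslinker
    turnover adds a forced-unbind rate).  Each free connector then attempts to
    bind with probability 1 - exp(-bind_rate * dt): a uniformly random bead is
    drawn and a partner bead on a different filament is chosen uniformly among
    those within the capture radius.
    """
    p = state.params
    if dt is None:
        dt = p.dt
    con = state.connectors
    rng = state.rng
    if len(con):
        rate = np.where(con.kind == KIND_MOTOR, p.unbind_rate_motor,
                        p.unbind_rate_crosslinker + p.crosslinker_turnover_rate)
        keep = rng.random(len(con)) >= 1.0 - np.exp(-rate * dt)
        con = con.select(keep)
        state.connectors = con
    p_bind = 1.0 - np.exp(-p.bind_rate * dt)
    n_free_xl = p.n_crosslinkers - con.count(KIND_CROSSLINKER)
    n_free_mo = p.n_motors - con.count(KIND_MOTOR)
    attempts = (int(rng.binomial(n_free_xl, p_bind)) if n_free_xl > 0 else 0,
                int(rng.binomial(n_free_mo, p_bind)) if n_free_mo > 0 else 0)
    total = attempts[0] + attempts[1]
    if total == 0:
        return state
    F, B = p.n_filaments, p.beads_per_filament
    if F == 0:
        return state
    coords = state.bead_coords()
    # cKDTree with box-size periodicity implements the minimum-image search
    tree = cKDTree(coords % p.box_size, boxsize=p.box_size)
    anchors = rng.integers(0, F * B, size=total)
    kinds = np.concatenate([np.zeros(attempts[0], np.int8),
                            np.ones(attempts[1], np.int8)])
    # one batched query per kind (kinds are ordered crosslinkers-then-motors)
    n_xl = int(np.sum(kinds == KIND_CROSSLINKER))
    neighbor_lists = []
    for sel, radius in ((slice(0, n_xl), p.capture_radius),
                        (slice(n_xl, None), p.motor_capture_radius)):
        pts = coords[anchors[sel]] % p.box_size
        if len(pts):
            neighbor_lists.extend(tree.query_ball_point(pts, radius))
    new_kind, new_fa, new_fb, new_sa, new_sb = [], [], [], [], []
    for anchor, kind, neigh in zip(anchors, kinds, neighbor_lists):
        fa = anchor // B
        partners = [j for j in neigh if j // B != fa]
        if not partners:
            continue
        j = partners[rng.integers(0, len(partners))]
        new_kind.append(kind)
        new_fa.append(fa)
        new_fb.append(j // B)
        new_sa.append((anchor % B) * p.bead_spacing)
        new_sb.append((j % B) * p.bead_spacing)
    if new_kind:
        added = Connectors(np.array(new_kind, np.int8),
                           np.array(new_fa, np.int32),
                           np.array(new_fb, np.int32),
                           np.array(new_sa, float),
                           np.array(new_sb, float),
                           np.zeros(len(new_kind)))
        state.connectors = state.connectors.extend(added)
    return state


def turnover_filaments(state: SimulationState, dt: float | None = None
                       ) -> SimulationState:
    """Whole-filament turnover: replace each filament with probability
    1 - exp(-rate * dt) by a fresh straight filament at a uniform random
    position and orientation, releasing its connectors.  Filament count is
    conserved."""
    p = state.params
    if dt is None:
        dt = p.dt
    if p.filament_turnover_rate <= 0 or p.n_filaments == 0:
        return state
    rng = state.rng
    prob = 1.0 - np.exp(-p.filament_turnover_rate * dt)
    renew = rng.random(p.n_filaments) < prob
    idx = np.flatnonzero(renew)
    if idx.size == 0:
        return state
    B = p.beads_per_filament
    centers = rng.uniform(0.0, p.box_size, size=(idx.size, 2))
    theta = rng.uniform(0.0, 2 * np.pi, size=idx.size)
    tangent = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    offsets = (np.arange(B) - (B - 1) / 2.0) * p.bead_spacing
    state.positions[idx] = (centers[:, None, :]
                            + offsets[None, :, None] * tangent[:, None, :]
                            ) % p.box_size
    con = state.connectors
    if len(con):
        gone = np.isin(con.fil_a, idx) | np.isin(con.fil_b, idx)
        state.connectors = con.select(~gone)
    return state


def run_condition(preset: ConditionPreset | SimulationParams,
                  overrides: dict | None = None,
                  snapshot_stride: float = 1.0,
                  connector_stride: int = 10,
                  progress: bool = False) -> Trajectory:
    """Run a condition to its configured duration, saving snapshots.

    ``connector_stride`` controls how many integration steps pass between
    connector-update / turnover sweeps (the stochastic rates are applied over
    the corresponding longer interval, so event statistics are unchanged).
    """
    if isinstance(preset, SimulationParams):
        params = preset.replace(**(overrides or {}))
    else:
        params = preset.params(**(overrides or {}))
    state = init_state(params)
    traj = Trajectory(params)
    traj.append(state)
    n_steps = int(round(params.duration / params.dt))
    snap_every = max(1, int(round(snapshot_stride / params.dt)))
    dt_conn = params.dt * connector_stride
    for i in range(1, n_steps + 1):
        if (i - 1) % connector_stride == 0:
            update_connectors(state, dt_conn)
            turnover_filaments(state, dt_conn)
        step(state)
        if i % snap_every == 0:
            traj.append(state)
    return traj
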
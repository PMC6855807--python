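"""Replica-exchange Gibbs sampling over poses, flexible beads and ψ.

The sampler is a Metropolis Monte Carlo walk over (i) rigid-body poses,
(ii) individual flexible-bead positions and (iii) the cross-link uncertainty
parameters ψ, run simultaneously at a ladder of temperatures with periodic
configuration swaps between adjacent rungs (parallel tempering).  The Gibbs
aspect is realized as interleaved parameter-class sweeps: one sweep attempts
several pose moves per rigid body, then one move per flexible bead, then one
per ψ class, each through the Metropolis test.

Move magnitudes follow the study conditions: rigid bodies translate by at
most 4 Å and rotate about a random axis by at most 0.03 rad per move,
flexible beads translate by at most 5 Å, and ψ receives Gaussian
perturbations reflected back into (ψ_min, 0.5].  Only frames of the coldest
replica are saved.

Scores are cached per term (per excluded-volume pair, per connectivity
tether, per cross-link) so a move only re-evaluates the terms its beads
touch; the cache is exactly consistent with a full re-evaluation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from xldock.representation import SystemModel
from xldock.scoring import PsiParameters, ScoreBreakdown, ScoreFunction
from xldock.xl_io import CrossLinkSet

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURES = tuple(np.geomspace(1.0, 2.5, 8))


@dataclass
class SamplerConfig:
    """Run parameters for replica-exchange sampling.

    Defaults mirror the production conditions (500,000 saved models from 100
    random starts, temperatures within [1.0, 2.5]); tests and the toy
    recovery runs scale ``n_models_total``/``n_starts`` down.
    """

    n_models_total: int = 500_000
    n_starts: int = 100
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES
    max_trans_rigid: float = 4.0  # Å
    max_rot_rigid: float = 0.03  # rad
    max_trans_bead: float = 5.0  # Å
    psi_move_sigma: float = 0.02
    swap_interval: int = 10  # sweeps between exchange attempts
    save_interval: int = 1  # sweeps between saved (coldest-replica) frames
    seed: int = 0
    psi_init: float = 0.05
    #: pose moves attempted per rigid body within one Gibbs sweep.  A body
    #: carries six pose degrees of freedom but would otherwise receive one
    #: proposal per sweep against dozens of single-bead proposals; several
    #: repeats per sweep give poses a sampling rate commensurate with their
    #: importance (the per-move magnitude caps are unchanged).
    body_moves_per_sweep: int = 5
    init_radius: float = 40.0  # Å, radius for random initial body placement
    #: bound (rad) on the random initial re-orientation of each body about
    #: the input model's pose; None draws orientations uniformly.  With
    #: rotational moves capped at 0.03 rad a replica traverses only ~1 rad
    #: of orientation space in a few thousand sweeps, so scaled-down runs
    #: are started within sampling reach of the input orientation — the
    #: position search (within ``init_radius``) is fully randomized.
    init_rot_max: float | None = 1.0

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        if len(temps) < 1 or np.any(np.diff(temps) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        for name in ("max_trans_rigid", "max_rot_rigid", "max_trans_bead", "psi_move_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_starts < 1 or self.n_models_total < 1:
            raise ValueError("n_models_total and n_starts must be positive")
        if self.body_moves_per_sweep < 1:
            raise ValueError("body_moves_per_sweep must be >= 1")
        if self.save_interval < 1 or self.swap_interval < 1:
            raise ValueError("save_interval and swap_interval must be >= 1")


@dataclass
class Move:
    """A single symmetric Monte Carlo proposal (not yet accepted)."""

    kind: str  # 'body' | 'bead' | 'psi'
    target: int  # body index, bead row, or psi-class index
    new_coords: np.ndarray | None = None  # replacement coords for moved beads
    bead_rows: np.ndarray | None = None  # rows replaced by new_coords
    new_psi: float | None = None
    translation: np.ndarray | None = None
    rotation_angle: float | None = None


class _EntityTerms:
    """Pre-sliced score-term index arrays touched by one movable entity."""

    __slots__ = ("ev_sel", "ev_i", "ev_j", "radsum",
                 "conn_sel", "conn_i", "conn_j",
                 "xl_sel", "xl_i", "xl_j", "xl_d0", "xl_class",
                 "new_ev", "new_conn", "new_xl")

    def __init__(self, sf: ScoreFunction, touched: np.ndarray):
        self.ev_sel = np.flatnonzero(touched[sf.ev_i] ^ touched[sf.ev_j])
        self.ev_i = sf.ev_i[self.ev_sel]
        self.ev_j = sf.ev_j[self.ev_sel]
        self.radsum = sf.radsum[self.ev_sel]
        self.conn_sel = np.flatnonzero(touched[sf.conn_i] ^ touched[sf.conn_j])
        self.conn_i = sf.conn_i[self.conn_sel]
        self.conn_j = sf.conn_j[self.conn_sel]
        self.xl_sel = np.flatnonzero(touched[sf.xl_i] ^ touched[sf.xl_j])
        self.xl_i = sf.xl_i[self.xl_sel]
        self.xl_j = sf.xl_j[self.xl_sel]
        self.xl_d0 = sf.xl_d0[self.xl_sel]
        self.xl_class = sf.xl_class[self.xl_sel]
        # scratch buffers for the candidate term values of one proposal
        self.new_ev = np.empty(len(self.ev_sel))
        self.new_conn = np.empty(len(self.conn_sel))
        self.new_xl = np.empty(len(self.xl_sel))


@njit(cache=True)
def _delta_kernel(coords, psi_vec,
                  ev_i, ev_j, radsum, k_ev, ev_sel, ev_terms, new_ev,
                  conn_i, conn_j, dmax, k_c, conn_sel, conn_terms, new_conn,
                  xl_i, xl_j, xl_d0, xl_cls, alpha, xl_sel, xl_terms, new_xl):
    """Candidate term values and score deltas for the terms one move touches.

    Writes candidate values into the ``new_*`` scratch buffers and returns
    (d_ev, d_conn, d_xl) relative to the cached per-term arrays."""
    d_ev = 0.0
    for k in range(ev_i.size):
        dx = coords[ev_i[k], 0] - coords[ev_j[k], 0]
        dy = coords[ev_i[k], 1] - coords[ev_j[k], 1]
        dz = coords[ev_i[k], 2] - coords[ev_j[k], 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        ov = radsum[k] - d
        v = k_ev * ov * ov if ov > 0.0 else 0.0
        new_ev[k] = v
        d_ev += v - ev_terms[ev_sel[k]]
    d_conn = 0.0
    for k in range(conn_i.size):
        dx = coords[conn_i[k], 0] - coords[conn_j[k], 0]
        dy = coords[conn_i[k], 1] - coords[conn_j[k], 1]
        dz = coords[conn_i[k], 2] - coords[conn_j[k], 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        st = d - dmax
        v = k_c * st * st if st > 0.0 else 0.0
        new_conn[k] = v
        d_conn += v - conn_terms[conn_sel[k]]
    d_xl = 0.0
    for k in range(xl_i.size):
        dx = coords[xl_i[k], 0] - coords[xl_j[k], 0]
        dy = coords[xl_i[k], 1] - coords[xl_j[k], 1]
        dz = coords[xl_i[k], 2] - coords[xl_j[k], 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        f = 1.0 / (1.0 + np.exp(alpha * (d - xl_d0[k])))
        psi = psi_vec[xl_cls[k]]
        v = -np.log(psi + (1.0 - 2.0 * psi) * f)
        new_xl[k] = v
        d_xl += v - xl_terms[xl_sel[k]]
    return d_ev, d_conn, d_xl


@njit(cache=True)
def _apply_kernel(ev_sel, ev_terms, new_ev, conn_sel, conn_terms, new_conn,
                  xl_sel, xl_terms, new_xl):
    for k in range(ev_sel.size):
        ev_terms[ev_sel[k]] = new_ev[k]
    for k in range(conn_sel.size):
        conn_terms[conn_sel[k]] = new_conn[k]
    for k in range(xl_sel.size):
        xl_terms[xl_sel[k]] = new_xl[k]


class _MoveTable:
    """Per-entity bookkeeping: which score terms a move can change."""

    def __init__(self, sf: ScoreFunction, model: SystemModel):
        n = model.n_beads
        self.body_rows: list[np.ndarray] = []
        self.body_terms: list[_EntityTerms] = []
        for body in model.rigid_bodies:
            inb = np.zeros(n, dtype=bool)
            inb[body.indices] = True
            self.body_rows.append(np.asarray(body.indices))
            self.body_terms.append(_EntityTerms(sf, inb))
        self.flex_rows = np.concatenate(
            [seg.indices for seg in model.flexible_segments]
        ).astype(np.intp) if model.flexible_segments else np.array([], dtype=np.intp)
        self.bead_terms: dict[int, _EntityTerms] = {}
        for b in self.flex_rows:
            b = int(b)
            one = np.zeros(n, dtype=bool)
            one[b] = True
            self.bead_terms[b] = _EntityTerms(sf, one)
        self.psi_links: list[np.ndarray] = [
            np.flatnonzero(sf.xl_class == c) for c in range(len(sf.psi_classes))
        ]


class ReplicaState:
    """One replica: coordinates, ψ, cached per-term scores and a temperature.

    The cached totals are kept exactly consistent with the coordinates; the
    ``check_cache`` method re-evaluates from scratch and returns the largest
    absolute discrepancy.
    """

    def __init__(
        self,
        sf: ScoreFunction,
        moves: _MoveTable,
        coords: np.ndarray,
        psi_vec: np.ndarray,
        temperature: float,
        rng: np.random.Generator,
    ):
        self.sf = sf
        self.moves = moves
        self.coords = np.array(coords, dtype=float)
        self.psi_vec = np.array(psi_vec, dtype=float)
        self.temperature = float(temperature)
        self.rng = rng
        self.n_proposed = 0
        self.n_accepted = 0
        self._recompute_all()

    def _recompute_all(self) -> None:
        self.ev_terms = self.sf._ev_terms(self.coords)
        self.conn_terms = self.sf._conn_terms(self.coords)
        self.xl_terms = self.sf._xl_neglogp(self.coords, self.psi_vec)
        self.ev_total = float(self.ev_terms.sum())
        self.conn_total = float(self.conn_terms.sum())
        self.xl_total = float(self.xl_terms.sum())

    @property
    def total(self) -> float:
        return self.ev_total + self.conn_total + self.xl_total

    @property
    def score(self) -> ScoreBreakdown:
        return ScoreBreakdown(
            xl_negloglik=self.xl_total,
            excluded_volume=self.ev_total,
            connectivity=self.conn_total,
            psi_neglogprior=0.0,
        )

    def check_cache(self) -> float:
        """Max |cached − recomputed| over the three coordinate-dependent terms."""
        fresh = self.sf.evaluate(self.coords, self.psi_vec)
        return max(
            abs(fresh.excluded_volume - self.ev_total),
            abs(fresh.connectivity - self.conn_total),
            abs(fresh.xl_negloglik - self.xl_total),
        )


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect x into (lo, hi] (half-open handled by nudging off lo)."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    y = y if y <= width else 2.0 * width - y
    if y == 0.0:
        y = min(width, 1e-12)
    return lo + y


def _random_rotation(rng: np.random.Generator, max_angle: float) -> tuple[np.ndarray, float]:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    kx, ky, kz = axis
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    R = np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)
    return R, angle


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1.0 / 3.0)


def _make_body_move(state: ReplicaState, body_idx: int, cfg: SamplerConfig,
                    rng: np.random.Generator) -> Move:
    rows = state.moves.body_rows[body_idx]
    xyz = state.coords[rows]
    centroid = xyz.mean(axis=0)
    R, angle = _random_rotation(rng, cfg.max_rot_rigid)
    t = _random_in_ball(rng, cfg.max_trans_rigid)
    new_xyz = (xyz - centroid) @ R.T + centroid + t
    return Move(kind="body", target=body_idx, new_coords=new_xyz, bead_rows=rows,
                translation=t, rotation_angle=angle)


def _make_bead_move(state: ReplicaState, bead_row: int, cfg: SamplerConfig,
                    rng: np.random.Generator) -> Move:
    t = _random_in_ball(rng, cfg.max_trans_bead)
    rows = np.array([bead_row], dtype=np.intp)
    return Move(kind="bead", target=bead_row, new_coords=state.coords[rows] + t,
                bead_rows=rows, translation=t)


def _make_psi_move(state: ReplicaState, class_idx: int, cfg: SamplerConfig,
                   rng: np.random.Generator) -> Move:
    old = state.psi_vec[class_idx]
    new = _reflect(old + rng.normal(0.0, cfg.psi_move_sigma), state.sf.psi_min, 0.5)
    return Move(kind="psi", target=class_idx, new_psi=new)


def propose_move(state: ReplicaState, rng: np.random.Generator,
                 cfg: SamplerConfig | None = None) -> Move:
    """Draw one symmetric proposal: a body pose, bead position or ψ move.

    The mover is chosen uniformly over movable entities (bodies, flexible
    beads, ψ classes), so each entity is equally likely to be perturbed.
    """
    cfg = cfg or SamplerConfig(n_models_total=1, n_starts=1)
    n_bodies = len(state.moves.body_rows)
    n_beads = len(state.moves.flex_rows)
    n_psi = len(state.moves.psi_links)
    pick = int(rng.integers(0, n_bodies + n_beads + n_psi))
    if pick < n_bodies:
        return _make_body_move(state, pick, cfg, rng)
    if pick < n_bodies + n_beads:
        return _make_bead_move(state, int(state.moves.flex_rows[pick - n_bodies]), cfg, rng)
    return _make_psi_move(state, pick - n_bodies - n_beads, cfg, rng)


def metropolis_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """The Metropolis criterion: accept with probability min(1, exp(−Δ/T))."""
    if not np.isfinite(delta):
        logger.warning("non-finite score change %r: move auto-rejected", delta)
        return False
    if delta <= 0.0:
        return True
    return rng.random() < math.exp(-delta / temperature)


def _attempt(state: ReplicaState, move: Move, rng: np.random.Generator) -> bool:
    """Evaluate a move's score change, apply the Metropolis test, update caches."""
    sf, mv = state.sf, state.moves
    state.n_proposed += 1
    if move.kind == "psi":
        sel = mv.psi_links[move.target]
        trial_psi = state.psi_vec.copy()
        trial_psi[move.target] = move.new_psi
        new_terms = sf._xl_neglogp(state.coords, trial_psi, sel)
        delta = float(new_terms.sum() - state.xl_terms[sel].sum())
        if metropolis_accept(delta, state.temperature, rng):
            state.psi_vec = trial_psi
            state.xl_terms[sel] = new_terms
            state.xl_total += delta
            state.n_accepted += 1
            return True
        return False

    et = mv.body_terms[move.target] if move.kind == "body" else mv.bead_terms[move.target]

    rows = move.bead_rows
    coords = state.coords
    old_xyz = coords[rows].copy()
    coords[rows] = move.new_coords

    d_ev, d_conn, d_xl = _delta_kernel(
        coords, state.psi_vec,
        et.ev_i, et.ev_j, et.radsum, sf.k_ev, et.ev_sel, state.ev_terms, et.new_ev,
        et.conn_i, et.conn_j, sf.connect_dmax, sf.k_c, et.conn_sel, state.conn_terms,
        et.new_conn,
        et.xl_i, et.xl_j, et.xl_d0, et.xl_class, sf.alpha, et.xl_sel, state.xl_terms,
        et.new_xl,
    )
    if metropolis_accept(d_ev + d_conn + d_xl, state.temperature, rng):
        _apply_kernel(et.ev_sel, state.ev_terms, et.new_ev,
                      et.conn_sel, state.conn_terms, et.new_conn,
                      et.xl_sel, state.xl_terms, et.new_xl)
        state.ev_total += d_ev
        state.conn_total += d_conn
        state.xl_total += d_xl
        state.n_accepted += 1
        return True
    coords[rows] = old_xyz
    return False


def metropolis_step(state: ReplicaState, rng: np.random.Generator,
                    cfg: SamplerConfig | None = None) -> ReplicaState:
    """One random-scan Metropolis step: propose one move, accept or reject."""
    move = propose_move(state, rng, cfg)
    _attempt(state, move, rng)
    return state


def swap_probability(t_a: float, t_b: float, s_a: float, s_b: float) -> float:
    """Acceptance probability for exchanging configurations between rungs."""
    return min(1.0, math.exp((1.0 / t_a - 1.0 / t_b) * (s_a - s_b)))


def replica_exchange_swap(a: ReplicaState, b: ReplicaState,
                          rng: np.random.Generator) -> bool:
    """Attempt a configuration swap; temperatures stay with the rungs."""
    if rng.random() < swap_probability(a.temperature, b.temperature, a.total, b.total):
        for attr in ("coords", "psi_vec", "ev_terms", "conn_terms", "xl_terms",
                     "ev_total", "conn_total", "xl_total"):
            tmp = getattr(a, attr)
            setattr(a, attr, getattr(b, attr))
            setattr(b, attr, tmp)
        return True
    return False


def _sweep(state: ReplicaState, cfg: SamplerConfig, rng: np.random.Generator) -> None:
    """Systematic Gibbs sweep: every body, every flexible bead, every ψ class."""
    for _ in range(cfg.body_moves_per_sweep):
        for b in range(len(state.moves.body_rows)):
            _attempt(state, _make_body_move(state, b, cfg, rng), rng)
    for row in state.moves.flex_rows:
        _attempt(state, _make_bead_move(state, int(row), cfg, rng), rng)
    for c in range(len(state.moves.psi_links)):
        _attempt(state, _make_psi_move(state, c, cfg, rng), rng)


def randomize_configuration(model: SystemModel, rng: np.random.Generator,
                            radius: float = 40.0,
                            rot_max: float | None = None) -> np.ndarray:
    """Random initial configuration: bodies re-oriented and scattered in a
    sphere, flexible beads re-interpolated between their anchors.

    ``rot_max`` bounds the random re-orientation angle of each body about
    the input pose; None composes two half-turn rotations for an
    approximately uniform orientation."""
    coords = model.coords.copy()
    for body in model.rigid_bodies:
        xyz = coords[body.indices]
        centroid = xyz.mean(axis=0)
        if rot_max is None:
            R1, _ = _random_rotation(rng, math.pi)
            R2, _ = _random_rotation(rng, math.pi)
            R = R2 @ R1
        else:
            R, _ = _random_rotation(rng, rot_max)
        target = rng.uniform(-radius, radius, size=3)
        coords[body.indices] = (xyz - centroid) @ R.T + target
    for seg in model.flexible_segments:
        lo, hi = seg.residue_range
        left = model.residue_index.get((seg.component, lo - 1))
        right = model.residue_index.get((seg.component, hi + 1))
        n = seg.n_beads
        if left is not None and right is not None:
            frac = (np.arange(1, n + 1) / (n + 1))[:, None]
            path = coords[left] * (1 - frac) + coords[right] * frac
        else:
            anchor = coords[left] if left is not None else (
                coords[right] if right is not None else np.zeros(3))
            steps = rng.standard_normal((n, 3))
            steps *= 3.8 / np.linalg.norm(steps, axis=1, keepdims=True)
            path = anchor + np.cumsum(steps, axis=0)
        coords[seg.indices] = path + rng.normal(0.0, 1.0, size=(n, 3))
    return coords


@dataclass
class EnsembleRecord:
    """One saved frame of the coldest replica."""

    coords: np.ndarray
    psi: dict[str, float]
    score: ScoreBreakdown
    replica: int
    sweep: int
    start: int


@dataclass
class ScoredEnsemble:
    """Saved frames plus the configuration that produced them."""

    records: list[EnsembleRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def scores(self) -> np.ndarray:
        return np.array([r.score.total for r in self.records])

    def write_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps({
                    "start": r.start, "sweep": r.sweep, "replica": r.replica,
                    "psi": r.psi, **r.score.as_dict(),
                }) + "\n")


def run_sampling(
    system: SystemModel,
    xls: CrossLinkSet,
    cfg: SamplerConfig,
    psi: PsiParameters | None = None,
    **scoring_kwargs,
) -> ScoredEnsemble:
    """Run replica-exchange sampling and collect coldest-replica frames.

    ``cfg.n_models_total`` frames are produced in total, split evenly over
    ``cfg.n_starts`` independent runs from randomized initial configurations.
    Each run holds one replica per temperature rung; every
    ``cfg.save_interval`` sweeps the coldest replica's frame is saved, and
    every ``cfg.swap_interval`` sweeps configuration swaps are attempted
    between adjacent rungs.  Deterministic for a fixed ``cfg.seed``.
    """
    if cfg.n_models_total % cfg.n_starts != 0:
        raise ValueError(
            f"n_models_total={cfg.n_models_total} not divisible by n_starts={cfg.n_starts}"
        )
    models_per_start = cfg.n_models_total // cfg.n_starts
    if models_per_start < 1:
        raise ValueError("configuration saves zero models per start")
    sweeps_per_start = models_per_start * cfg.save_interval

    if psi is None:
        linkers = sorted({rec.linker for rec in xls})
        psi = PsiParameters(values={lk: cfg.psi_init for lk in linkers}, mode="per_linker")
    sf = ScoreFunction(system, xls, psi, **scoring_kwargs)
    moves = _MoveTable(sf, system)
    temps = [float(t) for t in cfg.temperatures]
    psi0 = sf.psi_vector(psi)

    records: list[EnsembleRecord] = []
    root_ss = np.random.SeedSequence(cfg.seed)
    start_seeds = root_ss.spawn(cfg.n_starts)
    for start in range(cfg.n_starts):
        child = start_seeds[start].spawn(len(temps) + 2)
        init_rng = np.random.default_rng(child[-2])
        swap_rng = np.random.default_rng(child[-1])
        replicas = []
        coords0 = randomize_configuration(system, init_rng, cfg.init_radius,
                                          cfg.init_rot_max)
        for r, T in enumerate(temps):
            replicas.append(ReplicaState(
                sf, moves, coords0, psi0, T, np.random.default_rng(child[r])
            ))
        swap_offset = 0
        n_swap_attempted = n_swap_accepted = 0
        for sweep in range(1, sweeps_per_start + 1):
            for rep in replicas:
                _sweep(rep, cfg, rep.rng)
            if sweep % cfg.swap_interval == 0 and len(replicas) > 1:
                for lo in range(swap_offset, len(replicas) - 1, 2):
                    n_swap_attempted += 1
                    if replica_exchange_swap(replicas[lo], replicas[lo + 1], swap_rng):
                        n_swap_accepted += 1
                swap_offset = 1 - swap_offset
            if sweep % cfg.save_interval == 0:
                cold = replicas[0]
                records.append(EnsembleRecord(
                    coords=cold.coords.copy(),
                    psi={c: float(v) for c, v in zip(sf.psi_classes, cold.psi_vec)},
                    score=cold.score,
                    replica=0,
                    sweep=sweep,
                    start=start,
                ))
        acc = sum(r.n_accepted for r in replicas) / max(1, sum(r.n_proposed for r in replicas))
        logger.info(
            "start %d: move acceptance %.3f, swap acceptance %.3f",
            start, acc, n_swap_accepted / max(1, n_swap_attempted),
        )

    metadata = {
        "config": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                   for k, v in vars(cfg).items()},
        "n_links": sf.n_links,
        "psi_classes": sf.psi_classes,
    }
    return ScoredEnsemble(records=records, metadata=metadata)
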
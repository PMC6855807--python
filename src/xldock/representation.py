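"""Coarse-grained system representation: rigid bodies and flexible bead strings.

Every modeled residue is represented by exactly one bead.  Beads belonging to
a crystallographically resolved region are placed on the Cα positions of a
source structure and move together as a rigid body; residues without a
structure (termini, inter-domain linkers) are independent beads forming a
flexible string.  Distances between residues — the quantity every cross-link
restraint and satisfaction metric consumes — are Euclidean Cα(bead)–Cα(bead)
distances.

The topology is declared in YAML::

    components:
      - {name: rabex5, length: 492}
      - {name: ubiquitin, length: 76}
    bodies:
      - name: NtH+Ub
        members:
          - {component: rabex5, range: [18, 71], pdb: nth.pdb, chain: A}
          - {component: ubiquitin, range: [1, 73], pdb: nth.pdb, chain: B}
      - name: core
        members:
          - {component: rabex5, range: [133, 368], pdb: core.pdb, chain: A}
        split_at: [229, 230]        # optional: split into two bodies with
                                    # flexible beads at these residues
    flexible:
      - {component: rabex5, range: [1, 17]}

A body with ``split_at`` is divided at the given residue range: the residues
before it and after it become independent rigid bodies and the listed
residues become flexible beads (the "split" variant of a catalytic core);
without the flag the whole range is one rigid body (the "fused" variant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

try:
    import gemmi
except ImportError:  # pragma: no cover
    gemmi = None

ResidueKey = tuple[str, int]

DEFAULT_BEAD_RADIUS = 3.0  # Å
CA_CA_SPACING = 3.8  # Å, consecutive-residue Cα distance in a trace


def _check_rotation(rotation: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=100 * tol):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=100 * tol):
        raise ValueError("rotation matrix must have det +1 (no reflection)")
    return rotation


@dataclass
class RigidBody:
    """A group of beads that move as one unit.

    ``members`` lists (component, inclusive 1-based residue range) pairs;
    ``indices`` are the rows of the owning model's coordinate array.
    """

    name: str
    members: list[tuple[str, tuple[int, int]]]
    indices: np.ndarray  # (n,) int, rows in SystemModel.coords

    @property
    def n_beads(self) -> int:
        return int(len(self.indices))

    def residues(self) -> list[ResidueKey]:
        out = []
        for comp, (lo, hi) in self.members:
            out.extend((comp, r) for r in range(lo, hi + 1))
        return out


@dataclass
class FlexibleSegment:
    """A string of independently movable one-residue beads."""

    component: str
    residue_range: tuple[int, int]
    indices: np.ndarray
    bead_radius: float = DEFAULT_BEAD_RADIUS

    @property
    def n_beads(self) -> int:
        return int(len(self.indices))


@dataclass
class SystemModel:
    """Bead coordinates plus the rigid/flexible bookkeeping.

    ``coords`` holds one 3D point (Å) per bead; ``residue_index`` maps
    (component, residue) → row in ``coords``.  Every declared residue is
    housed in exactly one rigid body or one flexible segment.
    """

    coords: np.ndarray  # (N, 3) float64, Å
    rigid_bodies: list[RigidBody]
    flexible_segments: list[FlexibleSegment]
    residue_index: dict[ResidueKey, int]
    bead_radii: np.ndarray  # (N,)
    component_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        self.bead_radii = np.asarray(self.bead_radii, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if len(self.bead_radii) != len(self.coords):
            raise ValueError("bead_radii length must match coords")

    @property
    def n_beads(self) -> int:
        return int(len(self.coords))

    def copy(self) -> "SystemModel":
        return SystemModel(
            coords=self.coords.copy(),
            rigid_bodies=self.rigid_bodies,
            flexible_segments=self.flexible_segments,
            residue_index=self.residue_index,
            bead_radii=self.bead_radii,
            component_lengths=self.component_lengths,
        )

    def body(self, name: str) -> RigidBody:
        for b in self.rigid_bodies:
            if b.name == name:
                return b
        raise KeyError(f"no rigid body named {name!r}")

    def bead(self, component: str, residue: int) -> int:
        key = (component, residue)
        if key not in self.residue_index:
            raise KeyError(f"residue {component}:{residue} is not housed in the model")
        return self.residue_index[key]

    def bead_of_body(self) -> np.ndarray:
        """Body id per bead (-1 for flexible beads)."""
        owner = np.full(self.n_beads, -1, dtype=int)
        for i, b in enumerate(self.rigid_bodies):
            owner[b.indices] = i
        return owner


def apply_transform(
    model: SystemModel,
    body: str,
    rotation: np.ndarray,
    translation: Sequence[float],
) -> SystemModel:
    """Rigidly move one body: x -> R x + t (rotation about the global origin).

    Mutates ``model`` in place and returns it.  Composition of two calls
    equals a single call with the composed transform.
    """
    rotation = _check_rotation(rotation)
    translation = np.asarray(translation, dtype=float)
    rb = model.body(body)
    model.coords[rb.indices] = model.coords[rb.indices] @ rotation.T + translation
    return model


def ca_distance(model: SystemModel, a: ResidueKey, b: ResidueKey) -> float:
    """Euclidean Cα–Cα (bead–bead) distance in Å between two residues."""
    ia = model.bead(*a)
    ib = model.bead(*b)
    return float(np.linalg.norm(model.coords[ia] - model.coords[ib]))


# ---------------------------------------------------------------------------
# Topology parsing and model construction
# ---------------------------------------------------------------------------


def _read_ca_coords(pdb_path: str | Path, chain: str, lo: int, hi: int) -> np.ndarray:
    """Cα coordinates for residues lo..hi (inclusive, by PDB seqid)."""
    if gemmi is None:  # pragma: no cover
        raise ImportError("gemmi is required to read PDB coordinate files")
    structure = gemmi.read_structure(str(pdb_path))
    structure.setup_entities()
    model = structure[0]
    found: dict[int, np.ndarray] = {}
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            seqid = res.seqid.num
            if lo <= seqid <= hi and seqid not in found:
                ca = res.find_atom("CA", "*")
                if ca is not None:
                    found[seqid] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    missing = [r for r in range(lo, hi + 1) if r not in found]
    if missing:
        raise ValueError(
            f"missing Cα in {pdb_path} chain {chain} for residue(s) "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    return np.array([found[r] for r in range(lo, hi + 1)])


def _normalize_topology(topology: Mapping) -> tuple[list[dict], list[dict]]:
    """Expand split_at flags; return (body specs, flexible specs)."""
    bodies: list[dict] = []
    flexible: list[dict] = [dict(f) for f in topology.get("flexible", [])]
    for spec in topology.get("bodies", []):
        spec = dict(spec)
        split = spec.pop("split_at", None)
        if split is None:
            bodies.append(spec)
            continue
        s_lo, s_hi = int(split[0]), int(split[1])
        if len(spec["members"]) != 1:
            raise ValueError("split_at is only supported for single-member bodies")
        member = dict(spec["members"][0])
        lo, hi = int(member["range"][0]), int(member["range"][1])
        if not (lo < s_lo <= s_hi < hi):
            raise ValueError(f"split_at {split} must lie strictly inside range [{lo}, {hi}]")
        for suffix, (a, b) in (("_a", (lo, s_lo - 1)), ("_b", (s_hi + 1, hi))):
            m = dict(member)
            m["range"] = [a, b]
            bodies.append({"name": spec["name"] + suffix, "members": [m]})
        flexible.append({"component": member["component"], "range": [s_lo, s_hi]})
    return bodies, flexible


def build_system(
    topology: Mapping | str | Path,
    pdb_dir: str | Path | None = None,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    seed: int = 0,
    coords_override: Mapping[str, np.ndarray] | None = None,
) -> SystemModel:
    """Build a :class:`SystemModel` from a topology config and PDB files.

    Parameters
    ----------
    topology
        Topology mapping or path to a YAML file (schema in the module
        docstring).
    pdb_dir
        Directory against which relative ``pdb`` paths are resolved.
    bead_radius
        Default bead radius in Å.
    seed
        Seed for the flexible-bead initialization jitter.
    coords_override
        Optional ``{body name: (n, 3) array}`` supplying rigid-body bead
        coordinates directly, bypassing PDB reading (used by the synthetic
        generator and tests).

    Rigid beads are placed at Cα positions.  Flexible beads are initialized
    on a straight path interpolated between their anchoring beads with a
    small Gaussian jitter (σ = 1 Å, seeded); a segment with no anchors is
    laid out as a random walk with 3.8 Å steps.
    """
    if isinstance(topology, (str, Path)):
        topo_path = Path(topology)
        with open(topo_path) as fh:
            topology = yaml.safe_load(fh)
        if pdb_dir is None:
            pdb_dir = topo_path.parent
    pdb_dir = Path(pdb_dir) if pdb_dir is not None else Path(".")
    rng = np.random.default_rng(seed)

    component_lengths = {
        str(c["name"]): int(c.get("length", 0)) for c in topology.get("components", [])
    }
    body_specs, flex_specs = _normalize_topology(topology)

    residue_index: dict[ResidueKey, int] = {}
    coords_list: list[np.ndarray] = []
    rigid_bodies: list[RigidBody] = []
    flexible_segments: list[FlexibleSegment] = []
    next_idx = 0

    def _claim(comp: str, lo: int, hi: int) -> np.ndarray:
        nonlocal next_idx
        if hi < lo:
            raise ValueError(f"empty residue range [{lo}, {hi}] for {comp}")
        idx = np.arange(next_idx, next_idx + (hi - lo + 1))
        for k, r in enumerate(range(lo, hi + 1)):
            key = (comp, r)
            if key in residue_index:
                raise ValueError(f"residue {comp}:{r} declared twice in topology")
            residue_index[key] = next_idx + k
        next_idx += hi - lo + 1
        return idx

    for spec in body_specs:
        members: list[tuple[str, tuple[int, int]]] = []
        body_idx_parts: list[np.ndarray] = []
        for member in spec["members"]:
            comp = str(member["component"])
            lo, hi = int(member["range"][0]), int(member["range"][1])
            members.append((comp, (lo, hi)))
            body_idx_parts.append(_claim(comp, lo, hi))
            if coords_override is not None and spec["name"] in coords_override:
                continue
            xyz = _read_ca_coords(pdb_dir / member["pdb"], str(member["chain"]), lo, hi)
            coords_list.append(xyz)
        indices = np.concatenate(body_idx_parts)
        if coords_override is not None and spec["name"] in coords_override:
            xyz = np.asarray(coords_override[spec["name"]], dtype=float)
            if len(xyz) != len(indices):
                raise ValueError(
                    f"coords_override for body {spec['name']!r} has {len(xyz)} beads, "
                    f"topology declares {len(indices)}"
                )
            coords_list.append(xyz)
        rigid_bodies.append(RigidBody(name=str(spec["name"]), members=members, indices=indices))

    flex_claims: list[tuple[dict, np.ndarray]] = []
    for spec in flex_specs:
        comp = str(spec["component"])
        lo, hi = int(spec["range"][0]), int(spec["range"][1])
        idx = _claim(comp, lo, hi)
        coords_list.append(np.zeros((len(idx), 3)))  # placeholder, filled below
        flex_claims.append(({"component": comp, "lo": lo, "hi": hi}, idx))
        flexible_segments.append(
            FlexibleSegment(component=comp, residue_range=(lo, hi), indices=idx, bead_radius=bead_radius)
        )

    coords = np.vstack(coords_list) if coords_list else np.zeros((0, 3))
    if len(coords) != next_idx:
        raise AssertionError("internal bookkeeping error: coordinate count mismatch")

    # initialize flexible beads between their sequence anchors
    for spec, idx in flex_claims:
        comp, lo, hi = spec["component"], spec["lo"], spec["hi"]
        left = residue_index.get((comp, lo - 1))
        right = residue_index.get((comp, hi + 1))
        n = len(idx)
        if left is not None and right is not None:
            frac = (np.arange(1, n + 1) / (n + 1))[:, None]
            path = coords[left] * (1 - frac) + coords[right] * frac
        elif left is not None or right is not None:
            anchor = coords[left if left is not None else right]
            steps = rng.standard_normal((n, 3))
            steps *= CA_CA_SPACING / np.linalg.norm(steps, axis=1, keepdims=True)
            path = anchor + np.cumsum(steps, axis=0)
            if right is not None and left is None:
                path = path[::-1]
        else:
            steps = rng.standard_normal((n, 3))
            steps *= CA_CA_SPACING / np.linalg.norm(steps, axis=1, keepdims=True)
            path = np.cumsum(steps, axis=0)
        coords[idx] = path + rng.normal(0.0, 1.0, size=(n, 3))

    radii = np.full(next_idx, float(bead_radius))
    return SystemModel(
        coords=coords,
        rigid_bodies=rigid_bodies,
        flexible_segments=flexible_segments,
        residue_index=residue_index,
        bead_radii=radii,
        component_lengths=component_lengths,
    )


# ---------------------------------------------------------------------------
# PDB / pose serialization
# ---------------------------------------------------------------------------

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _component_chains(model: SystemModel) -> dict[str, str]:
    comps: list[str] = []
    for key in model.residue_index:
        if key[0] not in comps:
            comps.append(key[0])
    return {c: _CHAIN_IDS[i % len(_CHAIN_IDS)] for i, c in enumerate(comps)}


def write_model_pdb(
    models: SystemModel | Iterable[SystemModel],
    path: str | Path,
) -> None:
    """Write bead model(s) as CA-only PDB (MODEL/ENDMDL per configuration)."""
    if isinstance(models, SystemModel):
        models = [models]
    models = list(models)
    chains = _component_chains(models[0])
    with open(path, "w") as fh:
        for m_i, model in enumerate(models, start=1):
            fh.write(f"MODEL     {m_i:4d}\n")
            serial = 1
            items = sorted(model.residue_index.items(), key=lambda kv: kv[1])
            for (comp, resnum), idx in items:
                x, y, z = model.coords[idx]
                fh.write(
                    f"ATOM  {serial:5d}  CA  ALA {chains[comp]}{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_model_pdb_coords(path: str | Path) -> list[np.ndarray]:
    """Read back the coordinate arrays of a CA-only multi-model PDB."""
    if gemmi is None:  # pragma: no cover
        raise ImportError("gemmi is required to read PDB files")
    structure = gemmi.read_structure(str(path))
    out = []
    for model in structure:
        xyz = []
        for ch in model:
            for res in ch:
                ca = res.find_atom("CA", "*")
                if ca is not None:
                    xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
        out.append(np.array(xyz))
    return out


def write_pose_json(model: SystemModel, path: str | Path) -> None:
    """Write all bead coordinates and the residue index as JSON."""
    payload = {
        "residues": [[comp, res, idx] for (comp, res), idx in model.residue_index.items()],
        "coords": model.coords.tolist(),
        "bodies": [
            {"name": b.name, "members": [[c, list(r)] for c, r in b.members]}
            for b in model.rigid_bodies
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
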
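"""Ground-truth toy systems and simulated datasets.

Real inputs to the pipeline — cross-link identifications, HDX-MS centroid
tables, fluorescence decay traces — come from instruments; this module
generates statistically analogous data from known ground truth so every
stage is testable end to end:

* a toy multidomain system of compact rigid bodies (Cα-trace beads, 3.8 Å
  consecutive spacing) joined by flexible linkers, with frozen random poses
  as ground truth;
* cross-links sampled from inter-body residue pairs that are close in the
  ground truth (true links, Cα–Cα ≤ 30 Å) plus a controlled fraction of
  decoys sampled from intra-body pairs farther than 45 Å — inside a rigid
  body the pair distance never changes, so decoys are unsatisfiable in any
  configuration — with quality fields that pass the identification filter;
* two-state HDX centroid tables with saturating-exponential reference
  uptake, known per-peptide deltas, Gaussian replicate noise and optional
  peptide dropout;
* single-exponential fluorescence decays with Gaussian noise.

All randomness flows from one master seed through named substreams, so each
dataset can be regenerated independently and bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xldock.hdx import PROTON_MASS, IsotopeEnvelope, n_exchangeable
from xldock.kinetics import FluorescenceTrace
from xldock.representation import SystemModel, build_system
from xldock.xl_io import CrossLinkRecord, CrossLinkSet

CA_SPACING = 3.8  # Å
TRUE_LINK_DMAX = 30.0  # Å
DECOY_DMIN = 45.0  # Å, far above the 34 Å satisfaction cutoff
BODY_SPACING = 14.0  # Å between consecutive body centroids in the truth
MIN_BODY_CLEARANCE = 6.5  # Å minimum inter-body bead distance in the truth

_SUBSTREAMS = {"system": 0, "xl": 1, "hdx": 2, "kinetics": 3}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _rng(master_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), _SUBSTREAMS[stream]])


@dataclass
class ToyGroundTruth:
    """A toy system with its frozen ground-truth configuration and labels."""

    system: SystemModel
    component: str
    master_seed: int
    body_residue_ranges: list[tuple[int, int]]
    true_pairs: list[tuple[int, int]] = field(default_factory=list)
    decoy_pairs: list[tuple[int, int]] = field(default_factory=list)
    true_deltas: dict[str, float] = field(default_factory=dict)
    true_k_obs: dict[str, float] = field(default_factory=dict)

    @property
    def coords(self) -> np.ndarray:
        return self.system.coords


def _compact_trace(n: int) -> np.ndarray:
    """A rod-shaped serpentine lattice Cα trace with exact 3.8 Å steps.

    The trace snakes through an a × b × c lattice with a small cross-section
    and a long axis (helix-bundle-like proportions), so a body's spatial
    extent is comparable to a cross-linker's reach and link anchor positions
    constrain its orientation."""
    if n >= 8:
        a, b = 2, 2
    else:
        a, b = 1, min(2, n)
    # snake order over one a x b layer: consecutive cells always adjacent
    layer = []
    for y in range(b):
        xs = range(a) if y % 2 == 0 else range(a - 1, -1, -1)
        layer.extend((x, y) for x in xs)
    pts = []
    z = 0
    while len(pts) < n:
        cells = layer if z % 2 == 0 else layer[::-1]
        for x, y in cells:
            pts.append((x, y, z))
            if len(pts) == n:
                break
        z += 1
    xyz = np.array(pts, dtype=float) * CA_SPACING
    return xyz - xyz.mean(axis=0)


def _random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-uniform orthogonal matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _arc_bridge(a: np.ndarray, b: np.ndarray, n: int, bulge: np.ndarray) -> np.ndarray:
    """n points on a circular arc from a to b with ~3.8 Å bead spacing.

    The arc's contour length is (n+1) Cα steps, so a linker whose contour
    exceeds the anchor gap forms a slack loop bulging toward ``bulge``
    instead of a compressed straight line (which would pile beads on top of
    each other)."""
    contour = (n + 1) * CA_SPACING
    chord = float(np.linalg.norm(b - a))
    if chord >= contour or chord < 1e-9:
        frac = (np.arange(1, n + 1) / (n + 1))[:, None]
        return a * (1 - frac) + b * frac
    # solve sin(x)/x = chord/contour for x = theta/2 by bisection
    ratio = chord / contour
    lo, hi = 1e-9, math.pi - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if math.sin(mid) / mid > ratio:
            lo = mid
        else:
            hi = mid
    half = 0.5 * (lo + hi)
    theta = 2.0 * half
    radius = contour / theta
    e1 = (b - a) / chord
    u = bulge - np.dot(bulge, e1) * e1
    u /= np.linalg.norm(u)
    center = 0.5 * (a + b) - radius * math.cos(half) * u
    v_a = a - center
    axis = np.cross(v_a, b - center)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9 * radius * radius:  # theta ~ pi: any axis in the plane works
        axis = np.cross(v_a, u)
        nrm = np.linalg.norm(axis)
    axis /= nrm
    if theta > math.pi:  # arc runs the long way round the circle
        axis = -axis
    pts = []
    for i in range(1, n + 1):
        phi = theta * i / (n + 1)
        # Rodrigues rotation of v_a about axis by phi
        v = (v_a * math.cos(phi)
             + np.cross(axis, v_a) * math.sin(phi)
             + axis * np.dot(axis, v_a) * (1 - math.cos(phi)))
        pts.append(center + v)
    return np.array(pts)


def make_toy_system(
    n_bodies: int = 3,
    residues_per_body: int = 60,
    linker_length: int = 15,
    seed: int = 0,
    body_spacing: float = BODY_SPACING,
) -> ToyGroundTruth:
    """Build the toy system and freeze its random configuration as truth.

    Bodies are compact Cα traces placed sequentially: each new body sits at
    a random direction ``body_spacing`` Å from the previous one, rejected
    and redrawn while any inter-body bead distance falls below
    ``MIN_BODY_CLEARANCE`` (the truth must be overlap-free so its own score
    is near-optimal).  Flexible linkers of ``linker_length`` one-residue
    beads bridge consecutive bodies.
    """
    if n_bodies < 1 or residues_per_body < 2 or (n_bodies > 1 and linker_length < 1):
        raise ValueError("nonpositive toy-system sizes")
    rng = _rng(seed, "system")
    component = "toy"

    placed: list[np.ndarray] = []
    body_ranges: list[tuple[int, int]] = []
    res = 1
    bodies_spec = []
    flex_spec = []
    for b in range(n_bodies):
        trace = _compact_trace(residues_per_body)
        for _attempt in range(5000):
            R = _random_rotation_matrix(rng)
            if b == 0:
                centroid = np.zeros(3)
            else:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                centroid = placed[-1].mean(axis=0) + direction * body_spacing
            xyz = trace @ R.T + centroid
            # every body pair must stay within cross-linkable range (so each
            # pair contributes restraints and the arrangement is identifiable
            # from the data) while keeping clearance between bead surfaces
            near_all = all(
                np.linalg.norm(centroid - other.mean(axis=0)) <= 1.3 * body_spacing
                for other in placed
            )
            clear = all(
                np.min(np.linalg.norm(xyz[:, None, :] - other[None, :, :], axis=2))
                >= MIN_BODY_CLEARANCE
                for other in placed
            )
            # the linker (contour (L+1)·3.8 Å) must be able to bridge the
            # previous body's C-terminal bead to this body's N-terminal bead
            bridgeable = (b == 0) or (
                np.linalg.norm(xyz[0] - placed[-1][-1])
                <= 0.8 * (linker_length + 1) * CA_SPACING
            )
            if near_all and clear and bridgeable:
                break
        else:
            raise RuntimeError("could not place toy bodies without overlap")
        placed.append(xyz)
        lo = res
        hi = res + residues_per_body - 1
        body_ranges.append((lo, hi))
        bodies_spec.append({
            "name": f"body{b}",
            "members": [{"component": component, "range": [lo, hi]}],
        })
        res = hi + 1
        if b < n_bodies - 1:
            flex_spec.append({"component": component, "range": [res, res + linker_length - 1]})
            res += linker_length

    total = res - 1
    topology = {
        "components": [{"name": component, "length": total}],
        "bodies": bodies_spec,
        "flexible": flex_spec,
    }
    overrides = {f"body{b}": placed[b] for b in range(n_bodies)}
    system = build_system(topology, coords_override=overrides,
                         seed=int(rng.integers(0, 2**31 - 1)))
    # ground-truth linker paths: slack circular arcs chosen (out of a few
    # random bulge directions) to stay clear of every rigid body
    body_xyz = np.vstack(placed)
    for seg in system.flexible_segments:
        lo, hi = seg.residue_range
        a = system.coords[system.residue_index[(component, lo - 1)]]
        b = system.coords[system.residue_index[(component, hi + 1)]]
        best_path, best_clear = None, -np.inf
        for _trial in range(20):
            path = _arc_bridge(a, b, seg.n_beads, rng.standard_normal(3))
            clear = float(np.min(np.linalg.norm(
                path[:, None, :] - body_xyz[None, :, :], axis=2)))
            if clear > best_clear:
                best_path, best_clear = path, clear
            if clear >= MIN_BODY_CLEARANCE:
                break
        system.coords[seg.indices] = best_path
    return ToyGroundTruth(
        system=system,
        component=component,
        master_seed=seed,
        body_residue_ranges=body_ranges,
    )


def simulate_crosslinks(
    truth: ToyGroundTruth,
    n_true: int = 40,
    n_decoy: int = 4,
    d_max: float = TRUE_LINK_DMAX,
    decoy_dmin: float = DECOY_DMIN,
    seed: int | None = None,
    inter_body_only: bool = True,
) -> CrossLinkSet:
    """Sample true and decoy cross-links from the ground-truth configuration.

    True links are drawn uniformly from residue pairs whose ground-truth
    Cα–Cα distance is ≤ ``d_max``, restricted (by default) to pairs spanning
    two different rigid bodies — intra-body links carry no docking
    information.  Decoys are drawn from pairs with ground-truth distance
    > ``decoy_dmin`` that lie *within* one rigid body, so their distance is
    pinned by body rigidity and no arrangement can satisfy them: they are
    pure noise for the ψ model to absorb, exactly the role false
    identifications play.  Quality fields are drawn so every record passes
    the identification filter; the emitted records are shuffled and
    unlabeled while the true/decoy bookkeeping is kept on ``truth``.
    """
    rng = _rng(truth.master_seed if seed is None else seed, "xl")
    model = truth.system
    coords = model.coords
    owner = model.bead_of_body()
    items = sorted(model.residue_index.items(), key=lambda kv: kv[1])
    residues = np.array([resnum for (_c, resnum), _i in items])
    rows = np.array([i for _k, i in items])

    iu, ju = np.triu_indices(len(rows), k=2)  # skip self and adjacent pairs
    d = np.linalg.norm(coords[rows[iu]] - coords[rows[ju]], axis=1)
    housed = (owner[rows[iu]] >= 0) & (owner[rows[ju]] >= 0)
    cross_body = housed & (owner[rows[iu]] != owner[rows[ju]])
    same_body = housed & (owner[rows[iu]] == owner[rows[ju]])
    true_ok = cross_body if inter_body_only else (cross_body | same_body)
    true_cand = np.flatnonzero(true_ok & (d <= d_max))
    decoy_cand = np.flatnonzero(same_body & (d > decoy_dmin))
    if len(true_cand) < n_true or len(decoy_cand) < n_decoy:
        raise ValueError(
            f"insufficient candidate pairs: {len(true_cand)} true (need {n_true}), "
            f"{len(decoy_cand)} decoy (need {n_decoy})"
        )
    true_sel = rng.choice(true_cand, size=n_true, replace=False)
    decoy_sel = rng.choice(decoy_cand, size=n_decoy, replace=False)

    truth.true_pairs = [
        (int(residues[iu[s]]), int(residues[ju[s]])) for s in true_sel
    ]
    truth.decoy_pairs = [
        (int(residues[iu[s]]), int(residues[ju[s]])) for s in decoy_sel
    ]

    records = []
    for r1, r2 in truth.true_pairs + truth.decoy_pairs:
        records.append(CrossLinkRecord(
            protein1=truth.component,
            residue1=r1,
            protein2=truth.component,
            residue2=r2,
            linker=str(rng.choice(["DSS", "DSG"])),
            id_score=float(rng.uniform(30.0, 50.0)),
            delta_s=float(rng.uniform(0.1, 0.9)),
            fdr=float(rng.uniform(0.001, 0.04)),
        ))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return CrossLinkSet(records=records, provenance={
        "source": "synthetic", "n_true": n_true, "n_decoy": n_decoy,
        "d_max": d_max, "decoy_dmin": decoy_dmin, "seed": truth.master_seed,
    })


# ---------------------------------------------------------------------------
# HDX
# ---------------------------------------------------------------------------


def tile_peptides(length: int, pep_len: int = 12, step: int = 6,
                  seed: int = 0) -> pd.DataFrame:
    """A synthetic overlapping peptide map tiling residues 1..length."""
    rng = _rng(seed, "hdx")
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    rows = []
    start = 1
    i = 0
    while start <= length:
        end = min(start + pep_len - 1, length)
        rows.append({
            "peptide": f"pep{i:03d}",
            "sequence": sequence[start - 1:end],
            "start": start,
            "end": end,
        })
        if end == length:
            break
        start += step
        i += 1
    return pd.DataFrame(rows)


def simulate_hdx(
    peptide_map: pd.DataFrame,
    true_deltas: dict[str, float],
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    timepoints: tuple[float, ...] = (10.0, 60.0, 300.0, 900.0),
    seed: int = 0,
    dropout: set[tuple[str, float]] | None = None,
    base_mass: float = 1200.0,
) -> pd.DataFrame:
    """Two-state centroid table with known per-peptide uptake offsets.

    The reference state ("apo") takes uptake from a saturating exponential
    ``u_max (1 − exp(−k_p t))`` with per-peptide rate and amplitude; the
    "variant" state is offset by ``true_deltas[peptide]`` (clipped at 0).
    Gaussian replicate noise of ``noise_sd`` Da is added to deuterated
    centroids; undeuterated rows are noise-free.  ``dropout`` names
    (peptide, timepoint) pairs absent from the variant state, emulating
    peptide disappearance.  Returns a long-form centroid table with states
    "undeuterated", "apo" and "variant".
    """
    rng = _rng(seed, "hdx")
    dropout = dropout or set()
    rows = []
    for _, pep in peptide_map.iterrows():
        n_exch = n_exchangeable(pep["sequence"])
        u_max = 0.6 * n_exch + rng.uniform(-0.5, 0.5)
        k_p = 10 ** rng.uniform(-2.5, -0.5)
        pep_base = base_mass + rng.uniform(0, 400)
        delta = float(true_deltas.get(pep["peptide"], 0.0))
        rows.append({
            "peptide": pep["peptide"], "sequence": pep["sequence"],
            "start": pep["start"], "end": pep["end"], "state": "undeuterated",
            "timepoint": 0.0, "replicate": 0, "centroid_mass": pep_base,
        })
        for t in timepoints:
            u_ref = u_max * (1.0 - math.exp(-k_p * t))
            for state, offset in (("apo", 0.0), ("variant", delta)):
                if state == "variant" and (pep["peptide"], t) in dropout:
                    continue
                u = max(0.0, u_ref + offset)
                for rep in range(1, n_replicates + 1):
                    rows.append({
                        "peptide": pep["peptide"], "sequence": pep["sequence"],
                        "start": pep["start"], "end": pep["end"], "state": state,
                        "timepoint": t, "replicate": rep,
                        "centroid_mass": pep_base + u + rng.normal(0.0, noise_sd),
                    })
    return pd.DataFrame(rows)


def simulate_labeling_envelopes(
    sequence: str,
    true_fraction: float = 0.7,
    back_exchange: float = 0.2,
    charge: int = 2,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[str, list[IsotopeEnvelope]]:
    """Isotope envelopes for an undeuterated, partially labeled and fully
    deuterated control sample of one peptide.

    The measured uptake of the labeled sample is
    ``true_fraction × n_exch × (1 − back_exchange)``; the control's is
    ``n_exch × (1 − back_exchange)``; their ratio recovers
    ``true_fraction`` after back-exchange normalization.
    """
    rng = _rng(seed, "hdx")
    n_exch = n_exchangeable(sequence)
    mono = 800.0 + 3.5 * len(sequence)  # synthetic neutral monoisotopic mass

    def _envelope(uptake_da: float, rep: int, state: str) -> IsotopeEnvelope:
        shift = uptake_da + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        masses = mono + shift + np.arange(5) * 1.00335  # isotopologue ladder
        mz = masses / charge + PROTON_MASS
        intensity = np.array([1.0, 0.8, 0.5, 0.25, 0.1])
        return IsotopeEnvelope(peptide="pep", charge=charge, mz=mz,
                               intensity=intensity, state=state, replicate=rep)

    labeled_uptake = true_fraction * n_exch * (1.0 - back_exchange)
    control_uptake = n_exch * (1.0 - back_exchange)
    return {
        "undeuterated": [_envelope(0.0, r, "undeuterated") for r in range(n_replicates)],
        "labeled": [_envelope(labeled_uptake, r, "labeled") for r in range(n_replicates)],
        "fully_deuterated": [_envelope(control_uptake, r, "fully_deuterated")
                             for r in range(n_replicates)],
    }


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def simulate_kinetics(
    true_k: dict[str, float],
    amplitude: float = 100.0,
    plateau: float = 20.0,
    noise_sd: float = 1.0,
    n_points: int = 60,
    t_max: float = 600.0,
    n_replicates: int = 3,
    seed: int = 0,
    enzyme_conc: dict[str, float] | None = None,
    additive_conc: dict[str, float] | None = None,
) -> list[FluorescenceTrace]:
    """Exponential mant-GDP release traces with Gaussian noise.

    ``true_k`` maps condition label → k_obs (s⁻¹); optional per-condition
    enzyme and additive concentrations (μM) ride along as metadata.
    """
    for cond, k in true_k.items():
        if not k > 0:
            raise ValueError(f"true k for {cond!r} must be > 0, got {k}")
    rng = _rng(seed, "kinetics")
    t = np.linspace(0.0, t_max, n_points)
    traces = []
    for cond in sorted(true_k):
        k = true_k[cond]
        for rep in range(1, n_replicates + 1):
            y = amplitude * np.exp(-k * t) + plateau
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=n_points)
            traces.append(FluorescenceTrace(
                time=t, signal=y, condition=cond,
                enzyme_conc=(enzyme_conc or {}).get(cond, float("nan")),
                additive_conc=(additive_conc or {}).get(cond, 0.0),
                replicate=rep,
            ))
    return traces
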
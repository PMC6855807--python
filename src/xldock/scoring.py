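"""Bayesian scoring of bead models against cross-link restraints.

The posterior probability of a model M given cross-link data D and prior
information I factorizes as p(M|D,I) ∝ p(D|M,I) p(M|I).  Scores are negative
log-probabilities, so lower is better and components add:

* cross-link likelihood — each cross-link n with Cα–Cα distance d_n is
  observed with probability ``p_n = ψ + (1 − 2ψ)·f(d_n)`` where the forward
  model ``f(d) = 1 / (1 + exp(α (d − d0)))`` is a logistic switch centred on
  the linker-dependent threshold d0 (the chemistry's Cα–Cα reach, see
  :data:`LINKER_D0`; steepness α = 0.3 Å⁻¹).
  ψ ∈ (0, 0.5] is the uncertainty of observing a cross-link: ψ → 0 trusts
  the data fully, ψ = 0.5 makes the restraint uninformative.  The term is
  ``−Σ_n log p_n``.
* excluded volume — a soft-sphere penalty ``k_ev Σ max(0, r_i + r_j − d_ij)²``
  over non-bonded bead pairs.  Pairs inside the same rigid body and pairs of
  sequence-consecutive residues are not counted: their distances are fixed
  (rigid) or governed by the connectivity term (bonded).
* connectivity — sequence-consecutive residues not held in the same rigid
  body are tethered with ``k_c max(0, d − d_max)²`` (d_max = 4.0 Å).
* ψ prior — uniform on (ψ_min, 0.5]; its negative log is a constant and is
  reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from xldock.representation import SystemModel
    from xldock.xl_io import CrossLinkSet

DEFAULT_D0 = 20.0  # Å, forward-model switching distance for unknown linkers
#: Per-linker switching distances: the Cα–Cα reach of the linker chemistry.
#: DSS/DSG lysine-lysine cross-links span up to ~34 Å Cα–Cα once both side
#: chains and backbone geometry are counted — the same distance at which a
#: link is scored as satisfied in the ensemble analysis.  A switch far below
#: the chemistry's real reach makes genuinely observed long links look like
#: noise, and the posterior then prefers the uninformative ψ → 0.5 mode over
#: docking; 20 Å is kept for the shorter-reach DSSO regime.
LINKER_D0 = {"DSS": 34.0, "DSG": 34.0, "DSSO": 20.0}
DEFAULT_ALPHA = 0.3  # Å^-1, forward-model steepness
DEFAULT_PSI_MIN = 0.01
DEFAULT_CONNECT_DMAX = 4.0  # Å
GLOBAL_PSI_CLASS = "global"


@dataclass
class PsiParameters:
    """Cross-link uncertainty parameters, one value per cross-link class.

    ``mode`` selects the class-assignment rule: ``per_linker`` (default, one
    ψ per linker chemistry) or ``global`` (a single ψ).  Values must lie in
    (ψ_min, 0.5].
    """

    values: dict[str, float]
    mode: str = "per_linker"
    psi_min: float = DEFAULT_PSI_MIN

    def __post_init__(self) -> None:
        if self.mode not in {"per_linker", "global"}:
            raise ValueError(f"unknown psi mode {self.mode!r}")
        for cls, v in self.values.items():
            if not (0.0 < v <= 0.5):
                raise ValueError(f"psi[{cls!r}] = {v} outside (0, 0.5]")

    def class_of(self, record) -> str:
        return record.linker if self.mode == "per_linker" else GLOBAL_PSI_CLASS

    @classmethod
    def single(cls, psi: float, psi_min: float = DEFAULT_PSI_MIN) -> "PsiParameters":
        return cls(values={GLOBAL_PSI_CLASS: psi}, mode="global", psi_min=psi_min)

    def copy(self) -> "PsiParameters":
        return PsiParameters(values=dict(self.values), mode=self.mode, psi_min=self.psi_min)


@dataclass
class ScoreBreakdown:
    """Additive components of the posterior score (negative log scale)."""

    xl_negloglik: float
    excluded_volume: float
    connectivity: float
    psi_neglogprior: float = 0.0
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (
            self.xl_negloglik + self.excluded_volume + self.connectivity + self.psi_neglogprior
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "xl_negloglik": self.xl_negloglik,
            "excluded_volume": self.excluded_volume,
            "connectivity": self.connectivity,
            "psi_neglogprior": self.psi_neglogprior,
            "total": self.total,
        }


def forward_model(d: np.ndarray, d0: float = DEFAULT_D0, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Probability of observing a cross-link at Cα distance d (logistic switch)."""
    return 1.0 / (1.0 + np.exp(alpha * (np.asarray(d, dtype=float) - d0)))


class ScoreFunction:
    """Precomputed evaluator for one (topology, cross-link set) pair.

    Precomputes the bead-pair index arrays for the excluded-volume and
    connectivity terms and the per-link bead indices, so that repeated
    evaluation (and incremental re-evaluation during Monte Carlo) is cheap.
    Pair bookkeeping depends only on the topology, never on coordinates, so
    one instance serves every configuration of the same system.
    """

    def __init__(
        self,
        model: "SystemModel",
        xls: "CrossLinkSet",
        psi: PsiParameters,
        d0: float | Mapping[str, float] | None = None,
        alpha: float = DEFAULT_ALPHA,
        k_ev: float = 1.0,
        k_c: float = 1.0,
        connect_dmax: float = DEFAULT_CONNECT_DMAX,
    ):
        if len(xls) == 0:
            raise ValueError("cross-link set is empty; nothing to score")
        self.alpha = float(alpha)
        self.k_ev = float(k_ev)
        self.k_c = float(k_c)
        self.connect_dmax = float(connect_dmax)
        self.psi_classes = sorted(psi.values)
        self._class_pos = {c: i for i, c in enumerate(self.psi_classes)}
        self.psi_min = psi.psi_min

        # --- cross-links -> bead index arrays -------------------------------
        xl_i, xl_j, xl_cls, d0s = [], [], [], []
        offenders = []
        for rec in xls:
            try:
                xl_i.append(model.bead(rec.protein1, rec.residue1))
                xl_j.append(model.bead(rec.protein2, rec.residue2))
            except KeyError:
                offenders.append(rec)
                continue
            cls = psi.class_of(rec)
            if cls not in self._class_pos:
                raise ValueError(f"cross-link class {cls!r} has no psi value")
            xl_cls.append(self._class_pos[cls])
            if d0 is None:
                d0s.append(LINKER_D0.get(rec.linker, DEFAULT_D0))
            elif isinstance(d0, Mapping):
                d0s.append(d0.get(rec.linker, DEFAULT_D0))
            else:
                d0s.append(float(d0))
        if offenders:
            names = ", ".join(
                f"{r.protein1}:{r.residue1}-{r.protein2}:{r.residue2}" for r in offenders[:5]
            )
            raise ValueError(
                f"{len(offenders)} cross-link(s) reference residues not housed in "
                f"the model: {names}"
            )
        self.xl_i = np.array(xl_i, dtype=np.intp)
        self.xl_j = np.array(xl_j, dtype=np.intp)
        self.xl_class = np.array(xl_cls, dtype=np.intp)
        self.xl_d0 = np.array(d0s, dtype=float)
        self.n_links = len(self.xl_i)

        # --- excluded-volume pairs -----------------------------------------
        n = model.n_beads
        owner = model.bead_of_body()
        iu, ju = np.triu_indices(n, k=1)
        same_body = (owner[iu] >= 0) & (owner[iu] == owner[ju])
        bonded = np.zeros(len(iu), dtype=bool)
        conn_i, conn_j = [], []
        for (comp, res), idx in model.residue_index.items():
            nxt = model.residue_index.get((comp, res + 1))
            if nxt is None:
                continue
            a, b = (idx, nxt) if idx < nxt else (nxt, idx)
            if owner[a] >= 0 and owner[a] == owner[b]:
                continue  # held rigid; no tether or EV needed
            conn_i.append(a)
            conn_j.append(b)
        bonded_set = set(zip(conn_i, conn_j))
        if bonded_set:
            pair_key = iu.astype(np.int64) * n + ju
            bonded_keys = np.array([a * n + b for a, b in bonded_set], dtype=np.int64)
            bonded = np.isin(pair_key, bonded_keys)
        keep = ~(same_body | bonded)
        self.ev_i = np.ascontiguousarray(iu[keep])
        self.ev_j = np.ascontiguousarray(ju[keep])
        self.radsum = np.ascontiguousarray(
            model.bead_radii[self.ev_i] + model.bead_radii[self.ev_j]
        )
        self.conn_i = np.array(conn_i, dtype=np.intp)
        self.conn_j = np.array(conn_j, dtype=np.intp)

    # -- term evaluation helpers -------------------------------------------

    def _ev_terms(self, coords: np.ndarray, sel: np.ndarray | slice = np.s_[:]) -> np.ndarray:
        i, j = self.ev_i[sel], self.ev_j[sel]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        overlap = np.maximum(0.0, self.radsum[sel] - d)
        return self.k_ev * overlap * overlap

    def _conn_terms(self, coords: np.ndarray, sel: np.ndarray | slice = np.s_[:]) -> np.ndarray:
        i, j = self.conn_i[sel], self.conn_j[sel]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        stretch = np.maximum(0.0, d - self.connect_dmax)
        return self.k_c * stretch * stretch

    def _xl_neglogp(
        self, coords: np.ndarray, psi_vec: np.ndarray, sel: np.ndarray | slice = np.s_[:]
    ) -> np.ndarray:
        i, j = self.xl_i[sel], self.xl_j[sel]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        f = 1.0 / (1.0 + np.exp(self.alpha * (d - self.xl_d0[sel])))
        psi = psi_vec[self.xl_class[sel]]
        p = psi + (1.0 - 2.0 * psi) * f
        return -np.log(p)

    def psi_vector(self, psi: PsiParameters) -> np.ndarray:
        return np.array([psi.values[c] for c in self.psi_classes], dtype=float)

    def evaluate(self, coords: np.ndarray, psi: PsiParameters | np.ndarray) -> ScoreBreakdown:
        """Full evaluation of every component for one configuration."""
        psi_vec = psi if isinstance(psi, np.ndarray) else self.psi_vector(psi)
        if np.any(psi_vec <= 0.0) or np.any(psi_vec > 0.5):
            raise ValueError(f"psi values {psi_vec} outside (0, 0.5]")
        return ScoreBreakdown(
            xl_negloglik=float(self._xl_neglogp(coords, psi_vec).sum()),
            excluded_volume=float(self._ev_terms(coords).sum()),
            connectivity=float(self._conn_terms(coords).sum()),
            psi_neglogprior=0.0,
        )


# ---------------------------------------------------------------------------
# Module-level operations (single-shot wrappers over ScoreFunction)
# ---------------------------------------------------------------------------


def crosslink_likelihood(
    model: "SystemModel",
    xls: "CrossLinkSet",
    psi: PsiParameters,
    d0: float | Mapping[str, float] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Negative log-likelihood of the cross-link data given the model."""
    sf = ScoreFunction(model, xls, psi, d0=d0, alpha=alpha)
    return float(sf._xl_neglogp(model.coords, sf.psi_vector(psi)).sum())


def excluded_volume(model: "SystemModel", k_ev: float = 1.0) -> float:
    """Soft-sphere overlap penalty over non-bonded, non-rigid bead pairs."""
    from xldock.representation import SystemModel  # noqa: F401

    n = model.n_beads
    owner = model.bead_of_body()
    iu, ju = np.triu_indices(n, k=1)
    same_body = (owner[iu] >= 0) & (owner[iu] == owner[ju])
    bonded = np.zeros(len(iu), dtype=bool)
    rev = {v: k for k, v in model.residue_index.items()}
    for k in range(len(iu)):
        ca, cb = rev[int(iu[k])], rev[int(ju[k])]
        if ca[0] == cb[0] and abs(ca[1] - cb[1]) == 1:
            bonded[k] = True
    keep = ~(same_body | bonded)
    i, j = iu[keep], ju[keep]
    d = np.linalg.norm(model.coords[i] - model.coords[j], axis=1)
    overlap = np.maximum(0.0, model.bead_radii[i] + model.bead_radii[j] - d)
    return float(k_ev * np.sum(overlap**2))


def connectivity(model: "SystemModel", d_max: float = DEFAULT_CONNECT_DMAX, k_c: float = 1.0) -> float:
    """Tether penalty for sequence-consecutive residues not in one rigid body."""
    owner = model.bead_of_body()
    total = 0.0
    for (comp, res), idx in model.residue_index.items():
        nxt = model.residue_index.get((comp, res + 1))
        if nxt is None:
            continue
        if owner[idx] >= 0 and owner[idx] == owner[nxt]:
            continue
        d = float(np.linalg.norm(model.coords[idx] - model.coords[nxt]))
        total += k_c * max(0.0, d - d_max) ** 2
    return total


def total_score(
    model: "SystemModel",
    xls: "CrossLinkSet",
    psi: PsiParameters,
    d0: float | Mapping[str, float] | None = None,
    alpha: float = DEFAULT_ALPHA,
    k_ev: float = 1.0,
    k_c: float = 1.0,
    connect_dmax: float = DEFAULT_CONNECT_DMAX,
) -> ScoreBreakdown:
    """Posterior score breakdown for one configuration."""
    sf = ScoreFunction(
        model, xls, psi, d0=d0, alpha=alpha, k_ev=k_ev, k_c=k_c, connect_dmax=connect_dmax
    )
    return sf.evaluate(model.coords, psi)
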
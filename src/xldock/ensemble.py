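"""Analysis of a scored model ensemble.

Selects the best-scoring solutions, clusters them by coordinate RMSD after
superposition of a reference domain, reports per-cluster precision (mean
RMSD of members to the cluster center, the member with the lowest mean RMSD
to the rest), and measures cross-link satisfaction: a cross-link counts as
satisfied by a model when its Cα–Cα distance is shorter than 34 Å.  Three
satisfaction fractions are reported per cluster: for the overall
best-scoring solution, the maximum over single cluster members, and the
aggregate over all members together (a link counting once it is satisfied
by at least one member).  A split-half diagnostic checks sampling
convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans

from xldock.representation import SystemModel
from xldock.sampling import EnsembleRecord, ScoredEnsemble
from xldock.xl_io import CrossLinkSet

DEFAULT_SATISFACTION_CUTOFF = 34.0  # Å, Cα–Cα
DEFAULT_TOP_N = 200
DEFAULT_K = 3


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def select_top_models(ensemble: ScoredEnsemble, n: int = DEFAULT_TOP_N) -> list[EnsembleRecord]:
    """The n best-scoring saved models, ties broken by (sweep, start, replica)."""
    if len(ensemble) < n:
        raise ValueError(f"ensemble has {len(ensemble)} records, need at least {n}")
    ranked = sorted(
        ensemble.records,
        key=lambda r: (r.score.total, r.sweep, r.start, r.replica),
    )
    return ranked[:n]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def superpose(
    model: np.ndarray,
    reference: np.ndarray,
    subset: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``model`` onto ``reference``.

    Parameters
    ----------
    model, reference
        (N, 3) coordinate arrays with matching rows.
    subset
        Row indices over which the fit and the returned RMSD are computed
        (default: all rows).  At least 3 non-collinear points are required.

    Returns
    -------
    rotation, translation, rmsd
        The proper rotation (det +1, reflections excluded) and translation
        such that ``model @ rotation.T + translation`` best matches
        ``reference``; RMSD is over the subset after superposition.
    """
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise ValueError(f"shape mismatch: {model.shape} vs {reference.shape}")
    idx = np.arange(len(model)) if subset is None else np.asarray(subset, dtype=np.intp)
    if len(idx) < 3:
        raise ValueError(f"superposition needs >= 3 points, got {len(idx)}")
    x = model[idx]
    y = reference[idx]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # Kabsch via SVD of the covariance, with the proper-rotation correction
    H = x0.T @ y0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set; superposition undefined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    rmsd = float(np.sqrt(np.mean(np.sum((x0 @ R.T - y0) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_after_superposition(
    model: np.ndarray,
    reference: np.ndarray,
    fit_subset: Sequence[int],
    measure_subset: Sequence[int] | None = None,
) -> float:
    """Superpose on ``fit_subset``; report RMSD over ``measure_subset`` (default all)."""
    R, t, _ = superpose(model, reference, fit_subset)
    aligned = model @ R.T + t
    idx = (np.arange(len(model)) if measure_subset is None
           else np.asarray(measure_subset, dtype=np.intp))
    return float(np.sqrt(np.mean(np.sum((aligned[idx] - reference[idx]) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Satisfaction
# ---------------------------------------------------------------------------


def _link_rows(model: SystemModel, xls: CrossLinkSet) -> tuple[np.ndarray, np.ndarray]:
    i = np.array([model.bead(r.protein1, r.residue1) for r in xls], dtype=np.intp)
    j = np.array([model.bead(r.protein2, r.residue2) for r in xls], dtype=np.intp)
    return i, j


def link_distances(coords: np.ndarray, model: SystemModel, xls: CrossLinkSet) -> np.ndarray:
    """Cα–Cα distance of every cross-link in one configuration."""
    i, j = _link_rows(model, xls)
    return np.linalg.norm(coords[i] - coords[j], axis=1)


def satisfaction_fraction(
    coords: np.ndarray,
    model: SystemModel,
    xls: CrossLinkSet,
    cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
) -> float:
    """Fraction of cross-links with Cα–Cα distance strictly below the cutoff."""
    if len(xls) == 0:
        raise ValueError("satisfaction fraction is undefined for an empty cross-link set")
    d = link_distances(coords, model, xls)
    return float(np.count_nonzero(d < cutoff) / len(d))


@dataclass
class SatisfactionReport:
    best_scoring_fraction: float
    max_single_conformer_fraction: float
    aggregate_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {
            "best_scoring_fraction": self.best_scoring_fraction,
            "max_single_conformer_fraction": self.max_single_conformer_fraction,
            "aggregate_fraction": self.aggregate_fraction,
        }


def satisfaction_report(
    cluster_coords: Sequence[np.ndarray],
    best_scoring_coords: np.ndarray,
    model: SystemModel,
    xls: CrossLinkSet,
    cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
) -> SatisfactionReport:
    """The three per-cluster satisfaction fractions.

    ``best_scoring_fraction`` uses the overall best-scoring solution;
    ``max_single_conformer_fraction`` is the maximum over cluster members;
    ``aggregate_fraction`` counts a link satisfied when at least one member
    satisfies it.
    """
    if len(cluster_coords) == 0:
        raise ValueError("cluster is empty")
    i, j = _link_rows(model, xls)
    if len(i) == 0:
        raise ValueError("empty cross-link set")
    member_fracs = []
    satisfied_any = np.zeros(len(i), dtype=bool)
    for coords in cluster_coords:
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        sat = d < cutoff
        member_fracs.append(float(sat.mean()))
        satisfied_any |= sat
    return SatisfactionReport(
        best_scoring_fraction=satisfaction_fraction(best_scoring_coords, model, xls, cutoff),
        max_single_conformer_fraction=float(max(member_fracs)),
        aggregate_fraction=float(satisfied_any.mean()),
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterReport:
    """k-means clustering of superposed models plus per-cluster statistics."""

    k: int
    assignments: np.ndarray  # (n_models,) cluster label per model
    center_indices: list[int]  # per cluster, index of the medoid model
    precision: list[float]  # Å, mean RMSD of members to the medoid
    populations: list[int]
    satisfaction: list[SatisfactionReport] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "assignments": self.assignments.tolist(),
            "center_indices": self.center_indices,
            "precision": self.precision,
            "populations": self.populations,
            "satisfaction": [s.as_dict() for s in self.satisfaction],
        }


def _pairwise_rmsd_to(coords_list: list[np.ndarray], member: int, others: np.ndarray) -> np.ndarray:
    ref = coords_list[member]
    return np.array([
        np.sqrt(np.mean(np.sum((coords_list[o] - ref) ** 2, axis=1))) for o in others
    ])


def cluster_models(
    models: Sequence[EnsembleRecord] | Sequence[np.ndarray],
    k: int = DEFAULT_K,
    reference_domain: Sequence[int] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    xls: CrossLinkSet | None = None,
    system: SystemModel | None = None,
    cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
) -> ClusterReport:
    """Group models by k-means on superposed coordinates.

    Every model is first superposed onto a common reference (the first model
    in ``models``, which by the selection convention is the best-scoring
    one) using the ``reference_domain`` bead rows; k-means then runs on the
    flattened Cα coordinates, whose Euclidean metric is proportional to
    coordinate RMSD.  The best of ``n_restarts`` seeded restarts by
    within-cluster sum of squares is kept.  Per cluster, the center is
    re-extracted as the medoid (the member with the lowest mean RMSD to its
    co-members) and the precision is the mean RMSD of members to that
    center.  When ``xls`` and ``system`` are given, the three satisfaction
    fractions are attached per cluster.
    """
    coords_list = [m.coords if isinstance(m, EnsembleRecord) else np.asarray(m, dtype=float)
                   for m in models]
    n = len(coords_list)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} models")
    ref = coords_list[0]
    fit_idx = (np.arange(len(ref)) if reference_domain is None
               else np.asarray(reference_domain, dtype=np.intp))
    aligned = []
    for xyz in coords_list:
        R, t, _ = superpose(xyz, ref, fit_idx)
        aligned.append(xyz @ R.T + t)
    X = np.array([a.ravel() for a in aligned])

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)

    center_indices: list[int] = []
    precision: list[float] = []
    populations: list[int] = []
    satisfaction: list[SatisfactionReport] = []
    best_coords = aligned[0]
    for c in range(k):
        members = np.flatnonzero(labels == c)
        populations.append(int(len(members)))
        if len(members) == 1:
            center_indices.append(int(members[0]))
            precision.append(0.0)
        else:
            mean_rmsd = []
            for m in members:
                others = members[members != m]
                mean_rmsd.append(_pairwise_rmsd_to(aligned, int(m), others).mean())
            medoid = int(members[int(np.argmin(mean_rmsd))])
            center_indices.append(medoid)
            others = members[members != medoid]
            precision.append(float(_pairwise_rmsd_to(aligned, medoid, others).mean()))
        if xls is not None and system is not None:
            satisfaction.append(satisfaction_report(
                [aligned[int(m)] for m in members], best_coords, system, xls, cutoff))
    return ClusterReport(
        k=k,
        assignments=labels,
        center_indices=center_indices,
        precision=precision,
        populations=populations,
        satisfaction=satisfaction,
    )


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    best_score_half1: float
    best_score_half2: float
    ks_statistic: float
    ks_pvalue: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "best_score_half1": self.best_score_half1,
            "best_score_half2": self.best_score_half2,
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "converged": self.converged,
        }


def compare_score_halves(
    s1: np.ndarray,
    s2: np.ndarray,
    ks_threshold: float = 0.1,
) -> ConvergenceReport:
    """Compare two score samples: per-half best score and a two-sample
    Kolmogorov–Smirnov test; non-converged when the KS statistic exceeds
    ``ks_threshold``."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    ks = ks_2samp(s1, s2)
    return ConvergenceReport(
        best_score_half1=float(s1.min()),
        best_score_half2=float(s2.min()),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        converged=bool(ks.statistic <= ks_threshold),
    )


def convergence_split(
    ensemble: ScoredEnsemble,
    seed: int = 0,
    ks_threshold: float = 0.1,
    by_start: bool = False,
) -> ConvergenceReport:
    """Split the ensemble into two equal halves and compare their scores.

    By default the split is random (seeded).  With ``by_start=True`` the
    halves are the records of the first half of sampling starts versus the
    rest, which detects independent runs stuck in different basins — a
    random split of a pooled bimodal ensemble would mix the modes evenly
    and hide them.
    """
    scores = ensemble.scores()
    if len(scores) < 2:
        raise ValueError("need at least 2 records for a split-half diagnostic")
    if by_start:
        starts = sorted({r.start for r in ensemble})
        first = set(starts[:max(1, len(starts) // 2)])
        mask = np.array([r.start in first for r in ensemble])
        s1, s2 = scores[mask], scores[~mask]
        if len(s1) == 0 or len(s2) == 0:
            raise ValueError("by_start split needs at least 2 distinct starts")
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(scores))
        half = len(scores) // 2
        s1, s2 = scores[perm[:half]], scores[perm[half:2 * half]]
    return compare_score_halves(s1, s2, ks_threshold)
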
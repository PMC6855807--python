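"""Hydrogen/deuterium-exchange MS: centroid masses, uptake and differentials.

Backbone amide hydrogens exchange with solvent deuterium at rates reporting
on structure: hydrogen-bonded, buried amides exchange slowly (protected),
exposed or dynamic ones quickly.  For each pepsin peptide the deuterium
uptake at a timepoint is the shift of the intensity-weighted centroid of its
isotope envelope relative to the undeuterated reference.  Back-exchange
during workup is corrected, when a fully deuterated control (long urea
incubation in deuterated buffer) is available, by expressing uptake as a
fraction of the control's uptake.

Differential analysis compares two states peptide-by-peptide and timepoint-
by-timepoint: a peptide is *protected* in the test state when its uptake is
significantly lower than in the reference (Welch t-test p < α and
|Δuptake| ≥ a magnitude floor), *deprotected* when higher, *no_change*
otherwise, and *missing* when the peptide is observed in only one state
(peptide disappearance is a reportable result, not an artifact).  Per-residue
means over covering peptides can be written into the B-factor column of a
bead PDB for structure mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from xldock.representation import SystemModel

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276  # Da

DEFAULT_ALPHA = 0.05
DEFAULT_MAGNITUDE_MIN = 0.5  # Da

UPTAKE_COLUMNS = [
    "peptide", "sequence", "start", "end", "state", "timepoint", "replicate",
    "centroid_mass", "uptake",
]


@dataclass
class IsotopeEnvelope:
    """One peptide isotope envelope: (m/z, intensity) peaks at one condition."""

    peptide: str
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    state: str = ""
    timepoint: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if len(self.mz) != len(self.intensity) or len(self.mz) == 0:
            raise ValueError("envelope needs matching, non-empty m/z and intensity arrays")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        if not np.any(self.intensity > 0):
            raise ValueError("envelope has no peak with positive intensity")


def centroid_mass(env: IsotopeEnvelope) -> float:
    """Neutral centroid mass: (intensity-weighted mean m/z − proton) × charge."""
    total = env.intensity.sum()
    if total <= 0:
        raise ValueError("all-zero intensities: centroid undefined")
    mz_bar = float(np.dot(env.mz, env.intensity) / total)
    return (mz_bar - PROTON_MASS) * env.charge


def n_exchangeable(sequence: str) -> int:
    """Number of exchange-competent backbone amides of a peptide.

    Standard convention: length − 1 (the N-terminal amide back-exchanges
    instantly) minus prolines beyond the second residue (no amide H).
    """
    seq = sequence.upper()
    return max(0, len(seq) - 1 - seq[2:].count("P"))


# ---------------------------------------------------------------------------
# Uptake tables
# ---------------------------------------------------------------------------


def envelopes_to_centroids(envelopes: Iterable[IsotopeEnvelope],
                           meta: dict | None = None) -> pd.DataFrame:
    """Long-form centroid table (one row per envelope)."""
    rows = []
    for env in envelopes:
        rows.append({
            "peptide": env.peptide,
            "state": env.state,
            "timepoint": env.timepoint,
            "replicate": env.replicate,
            "charge": env.charge,
            "centroid_mass": centroid_mass(env),
            **(meta or {}),
        })
    return pd.DataFrame(rows)


def uptake(
    centroids: pd.DataFrame,
    undeuterated_state: str = "undeuterated",
) -> pd.DataFrame:
    """Deuterium uptake per (peptide, state, timepoint, replicate).

    ``centroids`` must have columns peptide, state, timepoint, replicate,
    centroid_mass.  The undeuterated reference per peptide is the mean
    centroid over rows with ``state == undeuterated_state``.  Rows whose
    peptide lacks a reference are flagged (``missing_reference``) and get
    NaN uptake.  Replicate mean and SD per (peptide, state, timepoint) are
    available via :func:`replicate_stats`.
    """
    needed = {"peptide", "state", "timepoint", "replicate", "centroid_mass"}
    missing = needed - set(centroids.columns)
    if missing:
        raise ValueError(f"centroid table lacks column(s): {sorted(missing)}")
    refs = (
        centroids[centroids["state"] == undeuterated_state]
        .groupby("peptide")["centroid_mass"]
        .mean()
    )
    out = centroids[centroids["state"] != undeuterated_state].copy()
    out["reference_mass"] = out["peptide"].map(refs)
    out["missing_reference"] = out["reference_mass"].isna()
    n_missing = int(out["missing_reference"].sum())
    if n_missing:
        logger.warning("%d rows lack an undeuterated reference and are excluded", n_missing)
    out["uptake"] = out["centroid_mass"] - out["reference_mass"]
    return out


def replicate_stats(uptake_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean, SD and count per (peptide, state, timepoint)."""
    ok = uptake_table
    if "missing_reference" in uptake_table.columns:
        ok = uptake_table[~uptake_table["missing_reference"]]
    g = ok.groupby(["peptide", "state", "timepoint"])["uptake"]
    return g.agg(mean="mean", sd="std", n="count").reset_index()


def normalize_backexchange(
    uptake_da: float | np.ndarray,
    fully_deuterated_uptake: float,
    n_exch: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-exchange correction against a fully deuterated control.

    Returns ``(fraction, corrected_da)`` where ``fraction`` is uptake over
    the control's uptake and ``corrected_da = fraction × n_exch``.
    """
    if not fully_deuterated_uptake > 0:
        raise ValueError(
            f"fully deuterated control uptake must be > 0, got {fully_deuterated_uptake}"
        )
    fraction = np.asarray(uptake_da, dtype=float) / fully_deuterated_uptake
    return fraction, fraction * n_exch


# ---------------------------------------------------------------------------
# Differential analysis
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    peptide: str
    timepoint: float
    delta_uptake: float  # Da, state − reference
    p_value: float
    classification: str  # protected | deprotected | no_change | missing
    start: int | None = None
    end: int | None = None


def differential(
    state_table: pd.DataFrame,
    reference_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    magnitude_min: float = DEFAULT_MAGNITUDE_MIN,
) -> list[DifferentialResult]:
    """Classify per-peptide, per-timepoint uptake differences between states.

    Both tables need columns peptide, timepoint, replicate, uptake (plus
    optional start/end).  ``delta = mean(state) − mean(reference)``;
    significance is a two-sided Welch t-test.  ``protected`` requires
    ``delta < −magnitude_min`` and ``p < alpha``; ``deprotected`` the
    mirror image; a peptide/timepoint present on only one side is
    ``missing``.
    """
    def _key_groups(df: pd.DataFrame) -> dict:
        return {k: g for k, g in df.groupby(["peptide", "timepoint"])}

    ga, gb = _key_groups(state_table), _key_groups(reference_table)
    only_a = set(ga) - set(gb)
    only_b = set(gb) - set(ga)
    if only_a or only_b:
        logger.warning(
            "peptide universes differ: %d only in state, %d only in reference",
            len(only_a), len(only_b),
        )

    def _meta(g: pd.DataFrame) -> tuple:
        start = int(g["start"].iloc[0]) if "start" in g else None
        end = int(g["end"].iloc[0]) if "end" in g else None
        return start, end

    results: list[DifferentialResult] = []
    for key in sorted(set(ga) | set(gb)):
        pep, tp = key
        if key in ga and key in gb:
            a = ga[key]["uptake"].dropna().to_numpy()
            b = gb[key]["uptake"].dropna().to_numpy()
            start, end = _meta(ga[key])
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"peptide {pep!r} at t={tp}: need >= 2 replicates per state for testing"
                )
            delta = float(a.mean() - b.mean())
            p = float(ttest_ind(a, b, equal_var=False).pvalue)
            if delta < -magnitude_min and p < alpha:
                cls = "protected"
            elif delta > magnitude_min and p < alpha:
                cls = "deprotected"
            else:
                cls = "no_change"
            results.append(DifferentialResult(pep, float(tp), delta, p, cls, start, end))
        else:
            g = ga.get(key, gb.get(key))
            start, end = _meta(g)
            results.append(DifferentialResult(
                pep, float(tp), float("nan"), float("nan"), "missing", start, end))
    return results


# ---------------------------------------------------------------------------
# Structure mapping
# ---------------------------------------------------------------------------

NO_COVERAGE = 999.99  # sentinel B-factor for residues without peptide coverage


def residue_deltas(
    results: Sequence[DifferentialResult],
    component: str,
    model: SystemModel,
) -> dict[int, float]:
    """Per-residue mean delta uptake over covering peptides."""
    per_res: dict[int, list[float]] = {}
    for res in results:
        if res.start is None or res.end is None or not np.isfinite(res.delta_uptake):
            continue
        for r in range(res.start, res.end + 1):
            if (component, r) in model.residue_index:
                per_res.setdefault(r, []).append(res.delta_uptake)
    return {r: float(np.mean(v)) for r, v in per_res.items()}


def map_to_structure(
    results: Sequence[DifferentialResult],
    model: SystemModel,
    component: str,
    path: str | Path,
) -> dict[int, float]:
    """Write per-residue mean deltas into the B-factor column of a bead PDB.

    Residues without peptide coverage get the sentinel value
    :data:`NO_COVERAGE` so downstream coloring can single them out.
    Returns the per-residue delta mapping.
    """
    deltas = residue_deltas(results, component, model)
    items = sorted(model.residue_index.items(), key=lambda kv: kv[1])
    with open(path, "w") as fh:
        serial = 1
        for (comp, resnum), idx in items:
            x, y, z = model.coords[idx]
            b = deltas.get(resnum, NO_COVERAGE) if comp == component else NO_COVERAGE
            b = max(-99.99, min(999.99, b))
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA A{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00{b:6.2f}           C\n"
            )
            serial += 1
        fh.write("END\n")
    return deltas


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_centroid_table(path: str | Path) -> pd.DataFrame:
    """Read a long-form centroid CSV (peptide, state, timepoint, replicate,
    centroid_mass, optional start/end/sequence)."""
    df = pd.read_csv(path)
    needed = {"peptide", "state", "timepoint", "replicate", "centroid_mass"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"centroid table {path} lacks column(s): {sorted(missing)}")
    return df


def read_envelope_table(path: str | Path) -> list[IsotopeEnvelope]:
    """Read a long-form envelope CSV (peptide, charge, state, timepoint,
    replicate, mz, intensity; one peak per row)."""
    df = pd.read_csv(path)
    needed = {"peptide", "charge", "state", "timepoint", "replicate", "mz", "intensity"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"envelope table {path} lacks column(s): {sorted(missing)}")
    envelopes = []
    keys = ["peptide", "charge", "state", "timepoint", "replicate"]
    for (pep, z, state, tp, rep), g in df.groupby(keys):
        g = g.sort_values("mz")
        envelopes.append(IsotopeEnvelope(
            peptide=str(pep), charge=int(z), mz=g["mz"].to_numpy(),
            intensity=g["intensity"].to_numpy(), state=str(state),
            timepoint=float(tp), replicate=int(rep),
        ))
    return envelopes
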
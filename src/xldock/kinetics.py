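"""Nucleotide-exchange kinetics from mant-GDP release fluorescence traces.

A GEF catalyzes GDP release from its GTPase substrate; with the fluorescent
analog mant-GDP, release appears as an exponential fluorescence decay.  Each
trace is fit to a one-phase decay

    Y(t) = (Y0 − plateau) · exp(−k_obs · t) + plateau

yielding the observed pseudo-first-order rate constant k_obs (the decay fit
is used, rather than initial rates, because reactions can be past the
initial linear phase at the enzyme concentrations used).  Catalytic
efficiency is

    (k_obs − k_intr) / [GEF]

where k_intr is the intrinsic (uncatalyzed) release rate; units default to
μM⁻¹·s⁻¹.  Condition comparisons are fold changes of efficiency relative to
a reference with percentile-bootstrap confidence intervals over replicates,
and dose series are summarized by the Spearman rank correlation of
efficiency with additive concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP = 2000


@dataclass
class FluorescenceTrace:
    """One mant-GDP release time course."""

    time: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # arbitrary fluorescence units
    condition: str = ""
    enzyme_conc: float = float("nan")  # μM
    additive: str = ""
    additive_conc: float = 0.0  # μM
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.time) < 8:
            raise ValueError(f"trace needs >= 8 points, got {len(self.time)}")
        if len(self.time) != len(self.signal):
            raise ValueError("time and signal lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.signal))):
            raise ValueError("trace contains non-finite values")


@dataclass
class KineticsFit:
    """One-phase decay fit result for a single trace."""

    k_obs: float  # s^-1
    amplitude: float  # Y0 − plateau
    plateau: float
    k_obs_se: float
    amplitude_se: float
    plateau_se: float
    r_squared: float
    reliable: bool
    condition: str = ""
    enzyme_conc: float = float("nan")
    additive_conc: float = 0.0
    replicate: int = 0


def _one_phase(t, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * t) + plateau


def fit_one_phase_decay(trace: FluorescenceTrace) -> KineticsFit:
    """Least-squares one-phase decay fit.

    Initialization: Y0 = first point, plateau = last point, k = ln 2 over
    half the time range.  A fit is flagged unreliable (value still
    returned) when it fails to converge, the rate is not positive, or the
    rate's standard error exceeds the rate itself.
    """
    t, y = trace.time, trace.signal
    model = Model(_one_phase)
    params = model.make_params(
        y0=y[0],
        plateau=y[-1],
        k=np.log(2.0) / (0.5 * (t[-1] - t[0])),
    )
    params["k"].set(min=0.0)
    result = model.fit(y, params, t=t)

    k = float(result.params["k"].value)
    y0 = float(result.params["y0"].value)
    plateau = float(result.params["plateau"].value)
    ses = {
        name: float(result.params[name].stderr)
        if result.params[name].stderr is not None else float("nan")
        for name in ("k", "y0", "plateau")
    }
    ss_res = float(np.sum(result.residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    reliable = bool(
        result.success
        and k > 0
        and np.isfinite(ses["k"])
        and ses["k"] <= k
    )
    if not reliable:
        logger.warning(
            "unreliable one-phase decay fit for %r (k=%.3g, se=%.3g)",
            trace.condition, k, ses["k"],
        )
    return KineticsFit(
        k_obs=k,
        amplitude=y0 - plateau,
        plateau=plateau,
        k_obs_se=ses["k"],
        amplitude_se=ses["y0"],
        plateau_se=ses["plateau"],
        r_squared=r2,
        reliable=reliable,
        condition=trace.condition,
        enzyme_conc=trace.enzyme_conc,
        additive_conc=trace.additive_conc,
        replicate=trace.replicate,
    )


@dataclass
class CatalyticEfficiency:
    """(k_obs − k_intr) / [GEF], μM⁻¹·s⁻¹ by default."""

    value: float
    k_obs: float
    k_intr: float
    enzyme_conc: float  # μM


def catalytic_efficiency(k_obs: float, k_intr: float, enzyme_conc: float,
                         per_molar: bool = False) -> CatalyticEfficiency:
    """Catalytic efficiency; ``per_molar`` reports M⁻¹·s⁻¹ instead of μM⁻¹·s⁻¹."""
    if not enzyme_conc > 0:
        raise ValueError(f"enzyme concentration must be > 0 μM, got {enzyme_conc}")
    value = (k_obs - k_intr) / enzyme_conc
    if value < 0:
        logger.warning(
            "catalytic efficiency %.3g is negative (k_obs below intrinsic rate)", value
        )
    if per_molar:
        value *= 1e6
    return CatalyticEfficiency(value=value, k_obs=k_obs, k_intr=k_intr,
                               enzyme_conc=enzyme_conc)


# ---------------------------------------------------------------------------
# Condition comparisons
# ---------------------------------------------------------------------------


@dataclass
class FoldChange:
    condition: str
    fold_change: float
    ci_low: float
    ci_high: float
    n_replicates: int


def compare_conditions(
    efficiencies: Mapping[str, Sequence[float]],
    reference: str,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    ci: float = 0.95,
) -> list[FoldChange]:
    """Fold change of mean efficiency per condition relative to a reference.

    ``efficiencies`` maps condition → per-replicate efficiency values.  The
    confidence interval is a seeded percentile bootstrap over replicates of
    both numerator and denominator.
    """
    if reference not in efficiencies:
        raise ValueError(f"reference condition {reference!r} not present")
    ref_vals = np.asarray(efficiencies[reference], dtype=float)
    if not ref_vals.mean() > 0:
        raise ValueError(f"reference efficiency must be > 0, got mean {ref_vals.mean()}")
    rng = np.random.default_rng(seed)
    q_lo, q_hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    out = []
    for cond, vals in efficiencies.items():
        vals = np.asarray(vals, dtype=float)
        fc = float(vals.mean() / ref_vals.mean())
        boots = np.empty(n_boot)
        for b in range(n_boot):
            num = vals[rng.integers(0, len(vals), len(vals))].mean()
            den = ref_vals[rng.integers(0, len(ref_vals), len(ref_vals))].mean()
            boots[b] = num / den
        out.append(FoldChange(
            condition=cond,
            fold_change=fc,
            ci_low=float(np.quantile(boots, q_lo)),
            ci_high=float(np.quantile(boots, q_hi)),
            n_replicates=len(vals),
        ))
    return out


@dataclass
class DoseResponse:
    doses: list[float]
    efficiencies: list[float]
    spearman_rho: float
    spearman_p: float


def dose_response(efficiency_by_dose: Mapping[float, Sequence[float] | float]) -> DoseResponse:
    """Efficiency vs additive dose, summarized by Spearman rank correlation.

    A strictly concentration-dependent stimulation gives ρ = 1; a flat
    series gives ρ = 0.  At least 3 dose levels are required.
    """
    if len(efficiency_by_dose) < 3:
        raise ValueError(f"need >= 3 dose levels, got {len(efficiency_by_dose)}")
    doses, means = [], []
    for dose in sorted(efficiency_by_dose):
        vals = np.atleast_1d(np.asarray(efficiency_by_dose[dose], dtype=float))
        doses.append(float(dose))
        means.append(float(vals.mean()))
    if np.allclose(means, means[0]):
        rho, p = 0.0, 1.0  # all tied: no monotone association
    else:
        rho, p = spearmanr(doses, means)
    return DoseResponse(doses=doses, efficiencies=means,
                        spearman_rho=float(rho), spearman_p=float(p))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_trace_table(path: str | Path,
                     dialect: Mapping[str, str] | None = None) -> list[FluorescenceTrace]:
    """Read long-form trace CSV (time_s, signal, condition, replicate and
    optional enzyme_conc_um, additive, additive_conc_um columns)."""
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dict(dialect))
    needed = {"time_s", "signal", "condition", "replicate"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"trace table {path} lacks column(s): {sorted(missing)}")
    traces = []
    for (cond, rep), g in df.groupby(["condition", "replicate"]):
        g = g.sort_values("time_s")
        traces.append(FluorescenceTrace(
            time=g["time_s"].to_numpy(),
            signal=g["signal"].to_numpy(),
            condition=str(cond),
            enzyme_conc=float(g["enzyme_conc_um"].iloc[0]) if "enzyme_conc_um" in g else float("nan"),
            additive=str(g["additive"].iloc[0]) if "additive" in g else "",
            additive_conc=float(g["additive_conc_um"].iloc[0]) if "additive_conc_um" in g else 0.0,
            replicate=int(rep),
        ))
    return traces
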
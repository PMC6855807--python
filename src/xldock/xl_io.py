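"""Reading, validation and quality filtering of cross-linking-MS tables.

Cross-linking mass spectrometry identifies pairs of lysine residues bridged by
an NHS-ester linker (DSS, DSG, ...).  Search engines such as xQuest/xProphet
report each candidate pair with an identification score (``id_score``), a
delta-S value and an estimated FDR.  Only confidently identified pairs are
used as spatial restraints; the canonical quality filter retains records with

    id_score > 28  AND  delta_s < 0.95  AND  fdr < 0.05

(strict inequalities — boundary values are excluded).  After filtering, one
restraint is kept per unordered residue pair, the record with the highest
``id_score`` winning a duplicate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Canonical column order for the internal CSV dialect.
CANONICAL_COLUMNS = [
    "protein1",
    "residue1",
    "protein2",
    "residue2",
    "linker",
    "id_score",
    "delta_s",
    "fdr",
]

KNOWN_LINKERS = {"DSS", "DSG", "DSSO"}

# Default quality thresholds.
MIN_ID_SCORE = 28.0
MAX_DELTA_S = 0.95
MAX_FDR = 0.05


@dataclass(frozen=True)
class CrossLinkRecord:
    """One residue-pair cross-link identification.

    Residue positions are 1-based sequence positions. ``link_class`` is
    ``intra`` when both residues belong to the same protein, else ``inter``.
    """

    protein1: str
    residue1: int
    protein2: str
    residue2: int
    linker: str = "DSS"
    id_score: float = float("nan")
    delta_s: float = float("nan")
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.residue1 < 1 or self.residue2 < 1:
            raise ValueError(
                f"residue positions must be >= 1, got "
                f"{self.protein1}:{self.residue1} / {self.protein2}:{self.residue2}"
            )
        if (self.protein1, self.residue1) == (self.protein2, self.residue2):
            raise ValueError(
                f"self cross-link {self.protein1}:{self.residue1} is not a restraint"
            )
        if self.fdr == self.fdr and not (0.0 <= self.fdr <= 1.0):  # NaN-safe
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr}")

    @property
    def link_class(self) -> str:
        return "intra" if self.protein1 == self.protein2 else "inter"

    @property
    def unordered_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Canonical (sorted) endpoint pair, used for deduplication."""
        a = (self.protein1, self.residue1)
        b = (self.protein2, self.residue2)
        return (a, b) if a <= b else (b, a)


@dataclass
class CrossLinkSet:
    """An ordered collection of :class:`CrossLinkRecord` with provenance."""

    records: list[CrossLinkRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein1": r.protein1,
                "residue1": r.residue1,
                "protein2": r.protein2,
                "residue2": r.residue2,
                "linker": r.linker,
                "id_score": r.id_score,
                "delta_s": r.delta_s,
                "fdr": r.fdr,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _dedup(records: Iterable[CrossLinkRecord]) -> list[CrossLinkRecord]:
    """Keep one record per unordered residue pair, preferring max id_score."""
    best: dict = {}
    order: list = []
    for rec in records:
        key = rec.unordered_pair
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            old = best[key]
            # NaN id_score never beats a numeric one
            if rec.id_score == rec.id_score and not (
                old.id_score == old.id_score and old.id_score >= rec.id_score
            ):
                best[key] = rec
    return [best[k] for k in order]


def load_column_mapping(path: str | Path) -> dict[str, str]:
    """Load a YAML column-mapping config ({source column -> canonical field})."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise ValueError(f"column mapping {path} must be a mapping, got {type(mapping)}")
    return dict(mapping)


def parse_crosslink_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> CrossLinkSet:
    """Read a cross-link CSV/TSV into a deduplicated :class:`CrossLinkSet`.

    Parameters
    ----------
    path
        CSV or TSV file with one identification per row.
    dialect
        Optional mapping ``{source column name -> canonical field}`` for
        non-canonical exports (e.g. xQuest-style ``AbsPos1`` headers).  The
        canonical fields are the entries of :data:`CANONICAL_COLUMNS`; at
        minimum ``protein1``, ``residue1``, ``protein2`` and ``residue2``
        must be mapped or already present.
    sep
        Field separator; inferred from the extension when omitted
        (``.tsv``/``.tab`` → tab, else comma).

    Rows whose residue positions do not parse as positive integers are
    skipped with a log message.  Duplicate unordered residue pairs collapse
    to the record with the highest ``id_score``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"cross-link table {path} contains no data rows")

    if dialect:
        df = df.rename(columns=dict(dialect))

    mandatory = ["protein1", "residue1", "protein2", "residue2"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(
            f"cross-link table {path} is missing mandatory column(s): {', '.join(missing)}"
        )

    records: list[CrossLinkRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            r1 = int(str(row["residue1"]).strip())
            r2 = int(str(row["residue2"]).strip())
        except (TypeError, ValueError):
            n_skipped += 1
            logger.warning(
                "skipping row %d of %s: unparseable residue position (%r, %r)",
                idx,
                path.name,
                row["residue1"],
                row["residue2"],
            )
            continue

        def _num(col: str) -> float:
            if col not in row or pd.isna(row[col]):
                return float("nan")
            try:
                return float(row[col])
            except (TypeError, ValueError):
                return float("nan")

        linker = str(row["linker"]).strip() if "linker" in row and pd.notna(row.get("linker")) else "DSS"
        if linker not in KNOWN_LINKERS:
            linker = linker if linker else "other"
        try:
            records.append(
                CrossLinkRecord(
                    protein1=str(row["protein1"]).strip(),
                    residue1=r1,
                    protein2=str(row["protein2"]).strip(),
                    residue2=r2,
                    linker=linker,
                    id_score=_num("id_score"),
                    delta_s=_num("delta_s"),
                    fdr=_num("fdr"),
                )
            )
        except ValueError as exc:
            n_skipped += 1
            logger.warning("skipping row %d of %s: %s", idx, path.name, exc)

    deduped = _dedup(records)
    provenance = {
        "source": str(path),
        "rows_read": int(len(df)),
        "rows_skipped": n_skipped,
        "records_after_dedup": len(deduped),
    }
    return CrossLinkSet(records=deduped, provenance=provenance)


def filter_crosslinks(
    xls: CrossLinkSet,
    min_id_score: float = MIN_ID_SCORE,
    max_delta_s: float = MAX_DELTA_S,
    max_fdr: float = MAX_FDR,
) -> CrossLinkSet:
    """Apply the identification quality filter (strict inequalities).

    A record survives iff ``id_score > min_id_score`` and
    ``delta_s < max_delta_s`` and ``fdr < max_fdr``.  Records with a missing
    (NaN) quality value fail that criterion.  Returns a new set; the filter
    report (counts per criterion) is stored in the provenance.
    """
    for name, v in [("min_id_score", min_id_score), ("max_delta_s", max_delta_s), ("max_fdr", max_fdr)]:
        if not (v == v and abs(v) != float("inf")):
            raise ValueError(f"threshold {name} must be finite, got {v}")

    kept: list[CrossLinkRecord] = []
    fail_counts = {"id_score": 0, "delta_s": 0, "fdr": 0}
    for rec in xls.records:
        ok = True
        if not rec.id_score > min_id_score:
            fail_counts["id_score"] += 1
            ok = False
        if not rec.delta_s < max_delta_s:
            fail_counts["delta_s"] += 1
            ok = False
        if not rec.fdr < max_fdr:
            fail_counts["fdr"] += 1
            ok = False
        if ok:
            kept.append(rec)
    if not kept:
        logger.warning("cross-link filter removed every record (%d in)", len(xls))
    provenance = dict(xls.provenance)
    provenance["filter"] = {
        "min_id_score": min_id_score,
        "max_delta_s": max_delta_s,
        "max_fdr": max_fdr,
        "n_in": len(xls),
        "n_out": len(kept),
        "n_failing_per_criterion": fail_counts,
    }
    return CrossLinkSet(records=kept, provenance=provenance)


def write_crosslink_table(xls: CrossLinkSet, path: str | Path) -> None:
    """Write a :class:`CrossLinkSet` in the canonical CSV dialect."""
    xls.to_frame().to_csv(path, index=False)


def write_filter_report(xls: CrossLinkSet, path: str | Path) -> None:
    """Write the provenance/filter report as JSON."""
    with open(path, "w") as fh:
        json.dump(xls.provenance, fh, indent=2)
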
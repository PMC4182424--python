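"""From raw RPKM time courses to per-ortholog log fold-change vectors.

The preparation stage mirrors how replicate-free RNA-Seq time courses
are condensed before enrichment testing:

1. discard sequences whose RPKM is zero at every time point in both
   conditions (unexpressed transcripts carry no information);
2. drop sequences without a KEGG Orthology (K ID) annotation;
3. average the RPKM vectors of sequences sharing a K ID, elementwise
   and per condition, so each ortholog contributes one vector;
4. floor both conditions at a small threshold (default 0.1 RPKM) to
   tame the log at low read counts, then take the per-time log2 ratio
   treatment/control.

The result is a dense (n_orthologs x n_times) matrix of log2 fold
changes -- the rows that the enrichment stage resamples.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COND_COL = re.compile(r"^(control|treatment)_([0-9]+(?:\.[0-9]+)?)h$")


class InputValidationError(ValueError):
    """Raised when an expression table violates its declared shape."""


@dataclass
class RpkmTable:
    """A collection of per-sequence RPKM time courses in two conditions.

    Parameters
    ----------
    sequence_ids
        One identifier per sequence (contig/transcript).
    kids
        KEGG Orthology IDs (``K#####``); empty string for unannotated.
    control, treatment
        ``(n_sequences, n_times)`` arrays of RPKM values, non-negative.
    time_points
        Strictly increasing time labels in hours.
    """

    sequence_ids: np.ndarray
    kids: np.ndarray
    control: np.ndarray
    treatment: np.ndarray
    time_points: np.ndarray

    def __post_init__(self) -> None:
        self.sequence_ids = np.asarray(self.sequence_ids, dtype=object)
        self.kids = np.asarray(self.kids, dtype=object)
        self.control = np.asarray(self.control, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        n = len(self.sequence_ids)
        t = len(self.time_points)
        for name, arr in (("control", self.control), ("treatment", self.treatment)):
            if arr.shape != (n, t):
                raise InputValidationError(
                    f"{name} matrix has shape {arr.shape}, expected {(n, t)}"
                )
        if len(self.kids) != n:
            raise InputValidationError("kids length does not match sequence_ids")
        if t and np.any(np.diff(self.time_points) <= 0):
            raise InputValidationError("time_points must be strictly increasing")
        for name, arr in (("control", self.control), ("treatment", self.treatment)):
            bad = ~np.isfinite(arr) | (arr < 0)
            if bad.any():
                offender = self.sequence_ids[np.where(bad.any(axis=1))[0][0]]
                raise InputValidationError(
                    f"negative or non-finite {name} RPKM for sequence {offender!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def take(self, index: np.ndarray) -> "RpkmTable":
        return RpkmTable(
            self.sequence_ids[index],
            self.kids[index],
            self.control[index],
            self.treatment[index],
            self.time_points,
        )

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RpkmTable":
        """Build from a table with columns ``sequence_id``, ``kid`` and one
        ``control_<T>h`` / ``treatment_<T>h`` column per time point."""
        if "sequence_id" not in df.columns:
            raise InputValidationError("missing required column 'sequence_id'")
        times: dict[float, dict[str, str]] = {}
        for col in df.columns:
            m = _COND_COL.match(str(col))
            if m:
                times.setdefault(float(m.group(2)), {})[m.group(1)] = col
        if not times:
            raise InputValidationError(
                "no condition columns found (expected e.g. 'control_0h', 'treatment_24h')"
            )
        tp = sorted(times)
        for t in tp:
            for cond in ("control", "treatment"):
                if cond not in times[t]:
                    raise InputValidationError(
                        f"missing {cond} column for time point {t:g}h"
                    )
        kid_col = df["kid"] if "kid" in df.columns else pd.Series("", index=df.index)
        kids = kid_col.fillna("").astype(str).str.strip().to_numpy(dtype=object)
        control = df[[times[t]["control"] for t in tp]].to_numpy(dtype=float)
        treatment = df[[times[t]["treatment"] for t in tp]].to_numpy(dtype=float)
        return cls(
            df["sequence_id"].astype(str).to_numpy(dtype=object),
            kids,
            control,
            treatment,
            np.asarray(tp),
        )

    @classmethod
    def read(cls, path) -> "RpkmTable":
        """Read a delimited expression table; the delimiter (tab or comma)
        is sniffed from the header line."""
        with open(path, "rt", newline="") as fh:
            head = fh.readline()
            sep = "\t" if head.count("\t") >= head.count(",") else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "sequence_id": self.sequence_ids,
            "kid": self.kids,
        }
        for j, t in enumerate(self.time_points):
            cols[f"control_{t:g}h"] = self.control[:, j]
        for j, t in enumerate(self.time_points):
            cols[f"treatment_{t:g}h"] = self.treatment[:, j]
        return pd.DataFrame(cols)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class KidExpression:
    """Per-K-ID mean RPKM vectors (elementwise means over the sequences
    annotated with that K ID, separately per condition)."""

    kids: np.ndarray
    control_mean: np.ndarray
    treatment_mean: np.ndarray
    n_sequences: np.ndarray
    time_points: np.ndarray

    def __len__(self) -> int:
        return len(self.kids)


@dataclass
class FoldChangeTable:
    """Log2 fold-change vectors, one row per K ID, one column per time."""

    kids: list = field(default_factory=list)
    lfc: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    time_points: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.kids = list(self.kids)
        self.lfc = np.asarray(self.lfc, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        if self.lfc.shape != (len(self.kids), len(self.time_points)):
            raise InputValidationError(
                f"lfc shape {self.lfc.shape} does not match "
                f"({len(self.kids)} kids, {len(self.time_points)} times)"
            )
        if not np.isfinite(self.lfc).all():
            raise InputValidationError("fold-change matrix contains non-finite values")
        if len(set(self.kids)) != len(self.kids):
            raise InputValidationError("duplicate K IDs in fold-change table")

    def __len__(self) -> int:
        return len(self.kids)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def row(self, kid: str) -> np.ndarray:
        return self.lfc[self.kids.index(kid)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.lfc, columns=[f"lfc_{t:g}h" for t in self.time_points]
        )
        df.insert(0, "kid", self.kids)
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path) -> "FoldChangeTable":
        df = pd.read_csv(path, sep="\t")
        tcols = [c for c in df.columns if c.startswith("lfc_")]
        times = [float(c[len("lfc_"):].rstrip("h")) for c in tcols]
        return cls(df["kid"].astype(str).tolist(), df[tcols].to_numpy(), times)


# ---------------------------------------------------------------------------
# operations


def filter_all_zero(table: RpkmTable) -> RpkmTable:
    """Drop sequences whose RPKM is 0 at every time point in both conditions."""
    keep = (table.control > 0).any(axis=1) | (table.treatment > 0).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_all_zero: removed %d all-zero sequences", dropped)
    return table.take(keep)


def drop_unannotated(table: RpkmTable) -> RpkmTable:
    """Drop sequences with no K ID; the excluded count is logged."""
    keep = np.array([bool(k) for k in table.kids])
    dropped = int((~keep).sum())
    if dropped:
        logger.info("drop_unannotated: excluded %d sequences without a K ID", dropped)
    return table.take(keep)


def aggregate_by_kid(table: RpkmTable) -> KidExpression:
    """Average RPKM vectors of sequences sharing a K ID, per condition.

    Unannotated sequences are excluded (and counted in the log) before
    averaging.  Output order is first-appearance order of each K ID.
    """
    table = drop_unannotated(table)
    order: dict[str, int] = {}
    for k in table.kids:
        if k not in order:
            order[k] = len(order)
    kids = np.array(list(order), dtype=object)
    idx = np.array([order[k] for k in table.kids])
    t = table.n_times
    counts = np.bincount(idx, minlength=len(kids)).astype(float)
    control = np.zeros((len(kids), t))
    treatment = np.zeros((len(kids), t))
    np.add.at(control, idx, table.control)
    np.add.at(treatment, idx, table.treatment)
    control /= counts[:, None]
    treatment /= counts[:, None]
    return KidExpression(
        kids, control, treatment, counts.astype(int), table.time_points
    )


def log_fold_change(
    kidexp: KidExpression, floor: float = 0.1, log_base: float = 2.0
) -> FoldChangeTable:
    """Per-time log fold change of floored treatment over floored control.

    Both condition means are raised to at least ``floor`` before taking
    the log, which keeps every entry finite and damps ratios driven by
    very small read counts.
    """
    if not floor > 0:
        raise ValueError(f"floor must be positive, got {floor!r}")
    if not log_base > 1:
        raise ValueError(f"log base must exceed 1, got {log_base!r}")
    c = np.maximum(kidexp.control_mean, floor)
    s = np.maximum(kidexp.treatment_mean, floor)
    lfc = (np.log(s) - np.log(c)) / np.log(log_base)
    return FoldChangeTable(list(kidexp.kids), lfc, kidexp.time_points)


def prepare_fold_changes(
    table: RpkmTable, floor: float = 0.1, log_base: float = 2.0
) -> FoldChangeTable:
    """Full preparation chain: zero-filter, annotate-filter, average
    per K ID, floor + log fold change."""
    return log_fold_change(aggregate_by_kid(filter_all_zero(table)), floor, log_base)
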
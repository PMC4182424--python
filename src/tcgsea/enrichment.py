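"""Resampling gene set enrichment over time-course fold-change vectors.

Each gene set (a list of K IDs, typically one KEGG metabolic pathway)
is summarised by the column mean of its members' log2 fold-change
vectors: one mean per time point.  The null distribution is built by
repeatedly drawing the same number of rows, without replacement, from
the whole fold-change matrix and storing each draw's column mean as a
row of the background matrix ``B`` (default 6000 draws).  Significance
is assessed with a multivariate empirical CDF over ``B``: the
upper-tail p-value counts background mean vectors that dominate the
observed mean componentwise at every time point (with an add-one guard
so p is never exactly 0).

This is deliberately not the running-sum/Kolmogorov–Smirnov flavour of
GSEA: with a single unreplicated sample per condition there is no
within-gene variance to estimate, and the mean-vector resampling test
asks only whether a set's trajectory stands out from equally sized
random gene groups.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from tcgsea.expression_prep import FoldChangeTable

logger = logging.getLogger(__name__)

TAILS = ("upper", "lower", "two_sided")

# cap per-chunk scratch for the resampling keys at ~8M floats (64 MB)
_CHUNK_BUDGET = 8_000_000


class EmptyOverlapError(ValueError):
    """A gene set shares no K ID with the fold-change table."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    kids: tuple

    def __post_init__(self) -> None:
        kids = tuple(self.kids)
        if not kids:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        if len(set(kids)) != len(kids):
            raise ValueError(f"gene set {self.set_id!r} has duplicate K IDs")
        object.__setattr__(self, "kids", kids)


@dataclass
class SetMatrix:
    """Fold-change rows of the gene-set members present in the data."""

    set_id: str
    matrix: np.ndarray  # (m, T)
    member_kids: list

    @property
    def m(self) -> int:
        return self.matrix.shape[0]


@dataclass
class NullDistribution:
    """Resampled background: ``B[j]`` is the column mean of ``m`` rows
    drawn without replacement from the full fold-change matrix."""

    set_id: str
    B: np.ndarray  # (R, T)
    R: int
    seed: object = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape[0] != self.R:
            raise ValueError("B row count does not match R")


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    m: int
    observed_mean: np.ndarray
    ecdf_value: float
    p_value: float
    tail: str
    R: int
    p_adjusted: float | None = None
    significant: bool = False


@dataclass
class GseaOutcome:
    """Results for sets with data overlap, plus the skipped set IDs."""

    results: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    time_points: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"set_id": r.set_id, "name": r.name, "m": r.m}
            for t, v in zip(self.time_points, r.observed_mean):
                row[f"mean_lfc_{t:g}h"] = v
            row["ecdf_value"] = r.ecdf_value
            row["p_value"] = r.p_value
            if r.p_adjusted is not None:
                row["p_adjusted"] = r.p_adjusted
            row["significant"] = r.significant
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> list[GeneSet]:
    """Read GMT-style gene sets: ``set_id <TAB> name <TAB> K1 K2 ...``.

    Members may be whitespace-separated in one field or spread over
    further tab-separated fields (classic GMT)."""
    sets = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 tab fields")
            kids = [k for f in parts[2:] for k in f.split() if k]
            sets.append(GeneSet(parts[0], parts[1], tuple(dict.fromkeys(kids))))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "wt") as fh:
        for s in sets:
            fh.write(f"{s.set_id}\t{s.name}\t" + " ".join(s.kids) + "\n")


# ---------------------------------------------------------------------------
# core operations


def build_set_matrix(fc: FoldChangeTable, gs: GeneSet) -> SetMatrix:
    """Rows of ``fc`` whose K ID belongs to ``gs``, in ``fc`` order."""
    members = set(gs.kids)
    idx = [i for i, k in enumerate(fc.kids) if k in members]
    if not idx:
        raise EmptyOverlapError(
            f"gene set {gs.set_id!r} has no members in the fold-change data"
        )
    return SetMatrix(gs.set_id, fc.lfc[idx], [fc.kids[i] for i in idx])


def column_mean(matrix) -> np.ndarray:
    """Column mean of a set matrix: the set's mean trajectory."""
    m = matrix.matrix if isinstance(matrix, SetMatrix) else np.asarray(matrix, float)
    if m.shape[0] < 1:
        raise ValueError("cannot take the column mean of an empty matrix")
    return m.mean(axis=0)


def _derive_rng(seed, set_id: str | None = None) -> np.random.Generator:
    """Deterministic per-set substream: adding or reordering sets must
    not perturb any other set's resamples."""
    if isinstance(seed, np.random.Generator):
        return seed
    entropy = [int(seed) if seed is not None else 0]
    if set_id is not None:
        entropy.append(zlib.crc32(set_id.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def resample_null(
    fc: FoldChangeTable,
    m: int,
    R: int = 6000,
    seed=None,
    set_id: str = "",
    exclude_kids=None,
) -> NullDistribution:
    """Build the background matrix ``B`` of resampled column means.

    Each of the ``R`` iterations draws ``m`` distinct rows uniformly
    from the fold-change matrix (the tested set's own rows included,
    unless ``exclude_kids`` is given) and records their column mean.
    """
    # canonicalise row order by K ID so resampling (and hence every
    # p-value) is invariant to how the input table happened to be sorted
    keep = range(len(fc.kids))
    if exclude_kids:
        drop = set(exclude_kids)
        keep = (i for i in keep if fc.kids[i] not in drop)
    order = sorted(keep, key=lambda i: fc.kids[i])
    pool = fc.lfc[order]
    n = pool.shape[0]
    if not 1 <= m <= n:
        raise ValueError(
            f"set {set_id or '?'}: cannot draw m={m} rows without replacement "
            f"from a pool of {n}"
        )
    if R < 1:
        raise ValueError(f"iteration count R must be >= 1, got {R}")
    rng = _derive_rng(seed, set_id or None)
    B = np.empty((R, pool.shape[1]))
    if m == n:
        B[:] = pool.mean(axis=0)
    else:
        chunk = max(1, _CHUNK_BUDGET // n)
        for start in range(0, R, chunk):
            stop = min(start + chunk, R)
            keys = rng.random((stop - start, n))
            idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
            B[start:stop] = pool[idx].mean(axis=1)
    return NullDistribution(set_id, B, R, seed)


def mecdf_value(null: NullDistribution | np.ndarray, x) -> float:
    """Multivariate empirical CDF of the background at ``x``: the
    fraction of background rows componentwise <= ``x``."""
    B = null.B if isinstance(null, NullDistribution) else np.asarray(null, float)
    x = np.asarray(x, dtype=float)
    if x.shape != (B.shape[1],):
        raise ValueError(f"query vector has length {x.size}, B has {B.shape[1]} columns")
    return float(np.all(B <= x, axis=1).mean())


def enrichment_pvalue(
    null: NullDistribution,
    observed_mean,
    tail: str = "upper",
    set_id: str | None = None,
    name: str = "",
    m: int = 0,
) -> EnrichmentResult:
    """Dominance-counting p-value of the observed mean trajectory.

    upper: fraction of background rows componentwise >= the observed
    mean; lower: componentwise <=; two_sided: twice the smaller, capped
    at 1.  Counts use an add-one guard, ``p = (count + 1) / (R + 1)``,
    so the smallest reportable p is ``1/(R+1)``.  The raw multivariate
    ECDF value at the observed mean is reported alongside.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    x = np.asarray(observed_mean, dtype=float)
    B = null.B
    if x.shape != (B.shape[1],):
        raise ValueError(f"mean vector has length {x.size}, B has {B.shape[1]} columns")
    R = null.R
    n_upper = int(np.all(B >= x, axis=1).sum())
    n_lower = int(np.all(B <= x, axis=1).sum())
    p_upper = (n_upper + 1) / (R + 1)
    p_lower = (n_lower + 1) / (R + 1)
    if tail == "upper":
        p = p_upper
    elif tail == "lower":
        p = p_lower
    else:
        p = min(1.0, 2.0 * min(p_upper, p_lower))
    return EnrichmentResult(
        set_id=null.set_id if set_id is None else set_id,
        name=name,
        m=m,
        observed_mean=x,
        ecdf_value=n_lower / R,
        p_value=p,
        tail=tail,
        R=R,
    )


def run_gsea(
    fc: FoldChangeTable,
    sets,
    R: int = 6000,
    seed=None,
    tail: str = "upper",
    alpha: float = 0.05,
    adjust: bool = False,
    exclude_set_members: bool = False,
) -> GseaOutcome:
    """Test every gene set against the resampled background.

    Sets with no K ID in the data are skipped (with a warning) and
    listed in ``outcome.skipped``.  Results are sorted by p-value, ties
    broken by set ID.  ``adjust=True`` adds a Benjamini–Hochberg column;
    the ``significant`` flag always compares the raw p-value to
    ``alpha``.
    """
    if not sets:
        raise ValueError("no gene sets supplied")
    results: list[EnrichmentResult] = []
    skipped: list[str] = []
    for gs in sets:
        try:
            sm = build_set_matrix(fc, gs)
        except EmptyOverlapError:
            logger.warning(
                "gene set %s (%s) skipped: no members in the data", gs.set_id, gs.name
            )
            skipped.append(gs.set_id)
            continue
        mbar = column_mean(sm)
        null = resample_null(
            fc,
            sm.m,
            R=R,
            seed=seed,
            set_id=gs.set_id,
            exclude_kids=sm.member_kids if exclude_set_members else None,
        )
        res = enrichment_pvalue(null, mbar, tail=tail, name=gs.name, m=sm.m)
        results.append(res)
    results.sort(key=lambda r: (r.p_value, r.set_id))
    if adjust and results:
        adj = false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    for r in results:
        r.significant = r.p_value < alpha
    return GseaOutcome(results, skipped, fc.time_points, alpha)
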
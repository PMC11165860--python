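"""Richness-preserving randomization and significance of the observed indices.

The randomization shuffles species occurrences across grid cells while
preserving, exactly, (i) the species richness of every cell and (ii) the
range size (occupied-cell count) of every species.  Each draw places species
in descending range order into distinct cells sampled with probability
proportional to remaining per-cell richness capacity, then resolves any
leftovers with a bounded swap-repair phase; a draw whose repair fails is
rejected and redrawn from a fresh substream.  With a spatial constraint the
cells are partitioned into groups and the shuffle runs independently within
each group, so species stay inside the regions they originally occupied.

Null distributions are accumulated streamingly (n, sum, sum of squares and
tail counts per cell and metric), chunks merge by summation, and chunk
random streams are derived counter-style from ``(base_seed, chunk_index)``
so a run is reproducible for a fixed seed and chunk count.

Significance uses the standardized effect size SES = (obs - mean_null)/sd_null
(unbiased sd) and add-one rank p-values p = (1 + #{null >= obs}) / (1 + n),
with ties counted in both tails.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .metrics import NULL_METRICS, metric_matrix
from .phylo import PhyloTree, branch_ranges

log = logging.getLogger(__name__)

_MAX_SWAPS = 10_000
_MAX_REDRAWS = 100
_TIE_EPS = 1e-9


class InfeasibleConstraintError(ValueError):
    pass


def _randomize_block(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One richness- and range-preserving shuffle of an incidence block."""
    n_cells, n_species = A.shape
    richness = A.sum(axis=1)
    ranges = A.sum(axis=0)
    order = np.argsort(-ranges, kind="stable")

    for _attempt in range(_MAX_REDRAWS):
        out = np.zeros_like(A)
        capacity = richness.astype(np.int64).copy()
        for s in order:
            k = int(ranges[s])
            if k == 0:
                continue
            w = np.maximum(capacity, 0).astype(float)
            open_cells = np.flatnonzero(w > 0)
            if len(open_cells) >= k:
                p = w[open_cells] / w[open_cells].sum()
                chosen = rng.choice(open_cells, size=k, replace=False, p=p)
            else:
                # forced placement; the swap-repair phase fixes the overflow
                closed = np.flatnonzero(w <= 0)
                extra = rng.choice(closed, size=k - len(open_cells), replace=False)
                chosen = np.concatenate([open_cells, extra])
            out[chosen, s] = True
            capacity[chosen] -= 1

        if _repair(out, richness, rng):
            assert (out.sum(axis=1) == richness).all()
            assert (out.sum(axis=0) == ranges).all()
            return out
        log.info("swap-repair failed; redrawing iteration")
    raise RuntimeError("randomization failed after redraw budget")


def _repair(out: np.ndarray, richness: np.ndarray, rng: np.random.Generator) -> bool:
    """Move species from over-full to under-full cells; True on success."""
    excess = out.sum(axis=1) - richness
    for _ in range(_MAX_SWAPS):
        over = np.flatnonzero(excess > 0)
        if len(over) == 0:
            return True
        j = int(rng.choice(over))
        under = np.flatnonzero(excess < 0)
        sp_j = np.flatnonzero(out[j])
        rng.shuffle(sp_j)
        moved = False
        for s in sp_j:
            target = under[~out[under, s]]
            if len(target):
                j2 = int(rng.choice(target))
                out[j, s] = False
                out[j2, s] = True
                excess[j] -= 1
                excess[j2] += 1
                moved = True
                break
        if not moved:
            # swap with a balanced cell holding a species j lacks
            balanced = np.flatnonzero(excess == 0)
            rng.shuffle(balanced)
            done = False
            for j2 in balanced:
                s_out = np.flatnonzero(out[j2] & ~out[j])
                s_in = np.flatnonzero(out[j] & ~out[j2])
                if len(s_out) and len(s_in):
                    a = int(rng.choice(s_in))
                    b = int(rng.choice(s_out))
                    out[j, a] = False
                    out[j2, a] = True
                    out[j2, b] = False
                    out[j, b] = True
                    done = True
                    break
            if not done:
                return False
    return (out.sum(axis=1) == richness).all()


def rand_structured(
    matrix, rng: np.random.Generator, constraints: np.ndarray | None = None
):
    """One randomized PresenceMatrix (cells, species and records unchanged).

    ``constraints`` assigns each cell an integer group id; the shuffle then
    runs independently within each group.  Raises
    :class:`InfeasibleConstraintError` when the groups do not partition the
    cells.
    """
    A = matrix.A
    if A.shape[0] == 0:
        return matrix
    if constraints is None:
        A_new = _randomize_block(A, rng)
    else:
        constraints = np.asarray(constraints)
        if constraints.shape != (A.shape[0],):
            raise InfeasibleConstraintError(
                "constraint groups must assign exactly one group per cell"
            )
        A_new = np.zeros_like(A)
        for g in np.unique(constraints):
            sel = constraints == g
            block = A[sel]
            # within a group both marginal totals are the group's incidences
            if block.sum() != block.sum(axis=0).sum():
                raise InfeasibleConstraintError(f"group {g} marginals inconsistent")
            A_new[sel] = _randomize_block(block, rng)
    return matrix.with_incidence(A_new)


# ---------------------------------------------------------------------------
# streaming accumulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class NullAccumulator:
    """Streaming summaries of null metric distributions per (cell, metric)."""

    metric_names: tuple
    cells: np.ndarray
    observed: np.ndarray  # (cells, metrics)
    n: int = 0
    sum: np.ndarray | None = None
    sumsq: np.ndarray | None = None
    count_ge: np.ndarray | None = None
    count_le: np.ndarray | None = None
    base_seed: int | None = None
    chunks: int = 1

    def _init_arrays(self):
        shape = self.observed.shape
        self.sum = np.zeros(shape)
        self.sumsq = np.zeros(shape)
        self.count_ge = np.zeros(shape, dtype=np.int64)
        self.count_le = np.zeros(shape, dtype=np.int64)

    def update(self, null_values: np.ndarray):
        if self.sum is None:
            self._init_arrays()
        eps = _TIE_EPS * np.maximum(1.0, np.abs(self.observed))
        self.n += 1
        v = np.nan_to_num(null_values, nan=0.0)
        o = np.nan_to_num(self.observed, nan=0.0)
        self.sum += v
        self.sumsq += v * v
        self.count_ge += (v >= o - eps).astype(np.int64)
        self.count_le += (v <= o + eps).astype(np.int64)

    def merge(self, other: "NullAccumulator") -> "NullAccumulator":
        assert self.metric_names == other.metric_names
        if other.sum is None:
            return self
        if self.sum is None:
            self._init_arrays()
        self.n += other.n
        self.sum += other.sum
        self.sumsq += other.sumsq
        self.count_ge += other.count_ge
        self.count_le += other.count_le
        return self


def chunk_rng(base_seed: int, chunk_index: int) -> np.random.Generator:
    """Counter-style substream: reproducible per (base_seed, chunk)."""
    return np.random.default_rng(np.random.SeedSequence((base_seed, chunk_index)))


def run_nullmodel(
    matrix,
    tree: PhyloTree,
    iterations: int,
    base_seed: int,
    chunks: int = 1,
    tip_to_key=None,
    constraints: np.ndarray | None = None,
    assert_marginals: bool = False,
) -> NullAccumulator:
    """Randomize, recompute the metrics, and accumulate null summaries.

    The branch table (descendant sets) is built once and reused; per-branch
    occupied-cell ranges are recomputed inside every iteration because they
    change with the arrangement.
    """
    if iterations < 1 or chunks < 1:
        raise ValueError("iterations and chunks must be >= 1")
    bt = branch_ranges(tree, matrix, tip_to_key)
    observed = metric_matrix(matrix.A, matrix.records, bt)
    acc = NullAccumulator(
        metric_names=NULL_METRICS,
        cells=matrix.cells,
        observed=observed,
        base_seed=base_seed,
        chunks=chunks,
    )
    per_chunk = [iterations // chunks + (1 if c < iterations % chunks else 0) for c in range(chunks)]
    richness = matrix.A.sum(axis=1)
    ranges = matrix.A.sum(axis=0)
    for c, n_iter in enumerate(per_chunk):
        rng = chunk_rng(base_seed, c)
        for _ in range(n_iter):
            rnd = rand_structured(matrix, rng, constraints)
            if assert_marginals:
                assert (rnd.A.sum(axis=1) == richness).all()
                assert (rnd.A.sum(axis=0) == ranges).all()
            acc.update(metric_matrix(rnd.A, rnd.records, bt))
    return acc


def significance(acc: NullAccumulator, observed: pd.DataFrame | None = None) -> pd.DataFrame:
    """SES and rank p-values per cell and metric.

    ``observed`` (a MetricsTable) overrides the stored observed values when
    given; p = (1 + tail count) / (1 + n), so p is in [1/(n+1), 1].  SES is
    null (NaN) where the null variance is zero.
    """
    n = acc.n
    if n < 1:
        raise ValueError("accumulator is empty")
    obs = acc.observed
    if observed is not None:
        obs = observed.loc[
            [format(int(c), "016x") for c in acc.cells], list(acc.metric_names)
        ].to_numpy()
    mean = acc.sum / n
    if n > 1:
        var = np.maximum(acc.sumsq - n * mean**2, 0.0) / (n - 1)
    else:
        var = np.zeros_like(mean)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(sd > 0, (np.nan_to_num(obs, nan=0.0) - mean) / sd, np.nan)
    p_high = (1.0 + acc.count_ge) / (1.0 + n)
    p_low = (1.0 + acc.count_le) / (1.0 + n)

    cols = {}
    for j, name in enumerate(acc.metric_names):
        cols[f"{name}_ses"] = ses[:, j]
        cols[f"{name}_p_high"] = p_high[:, j]
        cols[f"{name}_p_low"] = p_low[:, j]
    return pd.DataFrame(
        cols, index=pd.Index([format(int(c), "016x") for c in acc.cells], name="cell")
    )


def two_tailed_flags(sig: pd.DataFrame, metric: str, alpha: float = 0.05) -> pd.Series:
    """Two-tailed significance flag: 2 * min(p_high, p_low) <= alpha."""
    p2 = 2.0 * np.minimum(sig[f"{metric}_p_high"], sig[f"{metric}_p_low"])
    return p2 <= alpha
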
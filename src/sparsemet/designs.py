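"""Sparse allocation of lines to environments and cross-validation masks.

A sparse-testing design assigns each of J lines (treatments) to a subset of
I environments (blocks), each of size k < J.  Two generators are provided:

* ``find_incomplete_block`` — an equireplicate incomplete-block design whose
  pairwise concurrence counts are made as uniform as possible by a seeded
  swap-descent; when a balanced incomplete block design (BIBD) exists and is
  found, every pair of lines co-occurs exactly lambda = r(k-1)/(J-1) times.
* ``random_allocation`` — sequential random fill of environments, each line
  capped at r environments (with a deterministic, logged fallback when a
  block cannot otherwise be completed).

``cv_partitions`` turns either generator into train/test masks over the
full line x environment grid such that every line is observed (trains) in
at least one environment — the "tested lines in tested environments"
cross-validation used for sparse multi-environment trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AllocationDesign",
    "CVPartition",
    "find_incomplete_block",
    "random_allocation",
    "cv_partitions",
]


@dataclass
class AllocationDesign:
    """Binary line x environment incidence with its balance diagnostics."""

    incidence: np.ndarray  # J x I, entries 0/1
    k: int
    method_tag: str
    objective_trace: list = field(default_factory=list)
    fallback_excess: dict = field(default_factory=dict)  # line index -> reps above cap

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=int)
        if self.incidence.ndim != 2 or not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence must be a binary J x I matrix")
        if not (self.incidence.sum(axis=0) == self.k).all():
            raise ValueError("every environment (column) must contain exactly k lines")

    @property
    def n_lines(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_envs(self) -> int:
        return self.incidence.shape[1]

    @property
    def replications(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    @property
    def concurrence(self) -> np.ndarray:
        return self.incidence @ self.incidence.T

    @property
    def n_plots(self) -> int:
        return int(self.incidence.sum())

    def concurrence_variance(self) -> float:
        """Sum of squared deviations of off-diagonal concurrences from their mean."""
        lam = self.concurrence
        off = lam[np.triu_indices_from(lam, k=1)]
        return float(((off - off.mean()) ** 2).sum())


@dataclass
class CVPartition:
    """One train/test split of the J x I cell grid."""

    train: np.ndarray  # J x I boolean, True = training cell
    line_ids: np.ndarray
    env_ids: np.ndarray
    partition_index: int
    seed: int
    allocation_tag: str = ""

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=bool)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.env_ids = np.asarray(self.env_ids, dtype=object)
        if self.train.shape != (len(self.line_ids), len(self.env_ids)):
            raise ValueError("train mask shape does not match id lists")
        if (self.train.sum(axis=1) == 0).any():
            bad = self.line_ids[self.train.sum(axis=1) == 0]
            raise ValueError(f"lines with no training environment: {list(bad[:5])}")

    @property
    def test(self) -> np.ndarray:
        return ~self.train

    def train_cells(self) -> list[tuple]:
        js, is_ = np.nonzero(self.train)
        return [(self.line_ids[j], self.env_ids[i]) for j, i in zip(js, is_)]

    def test_cells(self) -> list[tuple]:
        js, is_ = np.nonzero(~self.train)
        return [(self.line_ids[j], self.env_ids[i]) for j, i in zip(js, is_)]


# ---------------------------------------------------------------------------
# incomplete-block generator


def _initial_blocks(J: int, I: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random near-equireplicate start: cycle a shuffled line order into blocks.

    Copies of the same line sit exactly J positions apart in the laid-out
    sequence, so any window of k < J consecutive positions holds distinct
    lines and every block is duplicate-free.
    """
    order = rng.permutation(J)
    reps = math.ceil(I * k / J)
    seq = np.tile(order, reps)[: I * k]
    incidence = np.zeros((J, I), dtype=int)
    for b in range(I):
        incidence[seq[b * k : (b + 1) * k], b] = 1
    return incidence


def _min_objective(J: int, I: int, k: int) -> float:
    """Lower bound on the concurrence sum of squared deviations.

    Total off-diagonal concurrence is fixed at I*k*(k-1); the objective is
    minimal when it is spread as evenly as possible over the J*(J-1)/2 pairs.
    """
    n_pairs = J * (J - 1) // 2
    total = I * k * (k - 1) // 2
    mean = total / n_pairs
    q, rem = divmod(total, n_pairs)
    return rem * (q + 1 - mean) ** 2 + (n_pairs - rem) * (q - mean) ** 2


def _swap_descent(
    incidence: np.ndarray, max_sweeps: int, trace: list
) -> np.ndarray:
    """Greedy pairwise swaps minimizing concurrence variance; monotone descent.

    One sweep visits every pair of blocks and applies the best strictly
    improving swap found for that pair.  The descent stops at the first sweep
    with no accepted swap (a local optimum) or after max_sweeps sweeps.
    """
    J, I = incidence.shape
    lam = (incidence @ incidence.T).astype(float)
    off = lam[np.triu_indices(J, k=1)]
    lam_bar = off.mean()  # invariant under swaps: block sizes are fixed
    obj = float(((off - lam_bar) ** 2).sum())
    trace.append(obj)

    for _ in range(max_sweeps):
        improved = False
        for b1 in range(I - 1):
            for b2 in range(b1 + 1, I):
                in1 = incidence[:, b1] == 1
                in2 = incidence[:, b2] == 1
                t1 = np.nonzero(in1 & ~in2)[0]  # swappable out of b1
                t2 = np.nonzero(in2 & ~in1)[0]
                if len(t1) == 0 or len(t2) == 0:
                    continue
                M = lam - lam_bar
                # delta(a, b) for a in t1, b in t2; see concurrence algebra:
                # pairs (a, x) lose a count for x in t1\{a}, gain for x in t2\{b};
                # pairs (b, x) do the opposite; overlap lines cancel.
                row1 = M[:, t1].sum(axis=1)  # sum over x in t1
                row2 = M[:, t2].sum(axis=1)
                n1, n2 = len(t1), len(t2)
                da = (-2.0 * row1[t1] + n1) - (-2.0 * M[t1, t1] + 1.0)
                da += 2.0 * row2[t1] + n2
                db = (-2.0 * row2[t2] + n2) - (-2.0 * M[t2, t2] + 1.0)
                db += 2.0 * row1[t2] + n1
                # remove the x=b / x=a terms wrongly included in the gain sums
                cross = -2.0 * M[np.ix_(t1, t2)] - 2.0 * M[np.ix_(t2, t1)].T - 2.0
                delta = da[:, None] + db[None, :] + cross
                ia, ib = np.unravel_index(np.argmin(delta), delta.shape)
                best = float(delta[ia, ib])
                if best < -1e-9:
                    a, b = t1[ia], t2[ib]
                    incidence[a, b1], incidence[a, b2] = 0, 1
                    incidence[b, b2], incidence[b, b1] = 0, 1
                    lam = (incidence @ incidence.T).astype(float)
                    obj += best
                    trace.append(obj)
                    improved = True
        if not improved:
            break
    return incidence


def _ibd_incidence(
    J: int,
    I: int,
    k: int,
    rng: np.random.Generator,
    max_sweeps: int,
    n_restarts: int,
) -> tuple[np.ndarray, list]:
    target = _min_objective(J, I, k)
    best, best_obj, best_trace = None, np.inf, []
    for _ in range(max(1, n_restarts)):
        trace: list = []
        inc = _swap_descent(_initial_blocks(J, I, k, rng), max_sweeps, trace)
        obj = trace[-1]
        if obj < best_obj:
            best, best_obj, best_trace = inc, obj, trace
        if best_obj <= target + 1e-9:
            break
    return best, best_trace


def find_incomplete_block(
    J: int,
    I: int,
    k: int,
    seed: int = 0,
    max_sweeps: int = 200,
    n_restarts: int = 30,
) -> AllocationDesign:
    """Equireplicate incomplete-block design by seeded swap-descent.

    Requires I*k divisible by J so that every line can be replicated exactly
    r = I*k/J times, and k < J (otherwise blocks are complete and the design
    is not sparse).  The descent minimizes the variance of the pairwise
    concurrence counts; when an integer lambda = r(k-1)/(J-1) exists and the
    search reaches it, the result is a BIBD.  Balance is not guaranteed in
    general — the best design over ``n_restarts`` seeded restarts is returned.
    """
    if J < 2 or I < 2:
        raise ValueError("need at least 2 lines and 2 environments")
    if k >= J:
        raise ValueError(f"k={k} >= J={J}: complete blocks are not a sparse design")
    if (I * k) % J != 0:
        raise ValueError(
            f"I*k = {I * k} is not divisible by J = {J}; "
            "adjust k so each line can be equally replicated"
        )
    rng = np.random.default_rng(seed)
    incidence, trace = _ibd_incidence(J, I, k, rng, max_sweeps, n_restarts)
    return AllocationDesign(incidence, k=k, method_tag="IBD", objective_trace=trace)


# ---------------------------------------------------------------------------
# constrained-random generator


def _random_incidence(
    J: int, I: int, k: int, r_cap: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Sequentially fill I blocks of size k, each line capped at r_cap reps.

    Candidates for a block are lines currently in fewer than r_cap
    environments.  When fewer than k candidates remain, the shortfall is
    filled deterministically from the least-replicated remaining lines
    (ties by line index), allowing one extra replicate; the overflow is
    returned in the fallback log.
    """
    if k > J:
        raise ValueError(f"block size k={k} exceeds the number of lines J={J}")
    counts = np.zeros(J, dtype=int)
    incidence = np.zeros((J, I), dtype=int)
    for b in range(I):
        candidates = np.nonzero(counts < r_cap)[0]
        if len(candidates) >= k:
            chosen = rng.choice(candidates, size=k, replace=False)
        else:
            shortfall = k - len(candidates)
            others = np.nonzero(counts >= r_cap)[0]
            order = others[np.lexsort((others, counts[others]))]
            extra = order[:shortfall]
            if len(extra) < shortfall or (counts[extra] >= r_cap + 1).any():
                raise ValueError(
                    "infeasible allocation: cannot fill a block even allowing "
                    "one replicate above the cap"
                )
            chosen = np.concatenate([candidates, extra])
        incidence[chosen, b] = 1
        counts[chosen] += 1
    excess = {int(j): int(c - r_cap) for j, c in enumerate(counts) if c > r_cap}
    return incidence, excess


def random_allocation(J: int, I: int, r: int, seed: int = 0) -> AllocationDesign:
    """Random allocation with each line in (approximately) r environments.

    Block size is k = ceil(J*r/I); environments are filled one at a time
    with k lines drawn uniformly without replacement from those present in
    fewer than r environments.  Rejects k >= J (not sparse).
    """
    if not (1 <= r <= I):
        raise ValueError("need 1 <= r <= I")
    if J < 1:
        raise ValueError("need J >= 1")
    k = math.ceil(J * r / I)
    if k >= J:
        raise ValueError(
            f"k = ceil(J*r/I) = {k} >= J = {J}: every environment would hold "
            "all lines; not a sparse design"
        )
    rng = np.random.default_rng(seed)
    incidence, excess = _random_incidence(J, I, k, r, rng)
    return AllocationDesign(
        incidence, k=k, method_tag="Random", fallback_excess=excess
    )


# ---------------------------------------------------------------------------
# cross-validation partitions


def _enforce_min_one(incidence: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Swap zero-replicate lines into blocks in place of well-replicated ones."""
    counts = incidence.sum(axis=1)
    for j in np.nonzero(counts == 0)[0]:
        # block whose most-replicated member can spare a replicate
        donors = incidence * counts[:, None]
        b = int(np.argmax(donors.max(axis=0)))
        d = int(np.argmax(donors[:, b]))
        if counts[d] <= 1:
            raise ValueError("cannot guarantee one training environment per line")
        incidence[d, b] = 0
        incidence[j, b] = 1
        counts[d] -= 1
        counts[j] += 1
    return incidence


def cv_partitions(
    line_ids,
    env_ids,
    n_partitions: int = 10,
    train_frac: float = 0.5,
    allocation_method: str = "IBD",
    seed: int = 0,
    max_sweeps: int = 30,
    n_restarts: int = 3,
) -> list[CVPartition]:
    """Train/test masks where training cells form a sparse allocation.

    Each partition's training cells are an allocation of k = round(
    train_frac * J) lines per environment generated by the requested method
    (partition i is seeded with ``seed + i``); the complementary cells are
    the test set.  Every line trains in at least one environment.  With an
    even per-line budget (e.g. I = 4 environments at train_frac = 0.5) the
    incomplete-block method gives every line exactly train_frac * I training
    environments; with an odd budget the per-line counts differ by at most
    one while every environment keeps exactly k training lines.
    """
    line_ids = np.asarray(line_ids, dtype=object)
    env_ids = np.asarray(env_ids, dtype=object)
    J, I = len(line_ids), len(env_ids)
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if allocation_method not in ("IBD", "Random"):
        raise ValueError("allocation_method must be 'IBD' or 'Random'")
    k = int(round(train_frac * J))
    if k < 1 or I * k < J:
        raise ValueError(
            f"train_frac={train_frac} leaves too few training cells to observe "
            "every line at least once"
        )
    if k >= J:
        raise ValueError("train_frac too large: training blocks would be complete")
    r_cap = math.ceil(train_frac * I)

    out = []
    for p in range(n_partitions):
        part_seed = seed + p
        rng = np.random.default_rng(part_seed)
        if allocation_method == "IBD":
            incidence, _ = _ibd_incidence(J, I, k, rng, max_sweeps, n_restarts)
        else:
            incidence, _ = _random_incidence(J, I, k, r_cap, rng)
            incidence = _enforce_min_one(incidence, rng)
        out.append(
            CVPartition(
                train=incidence.astype(bool),
                line_ids=line_ids,
                env_ids=env_ids,
                partition_index=p,
                seed=part_seed,
                allocation_tag=allocation_method,
            )
        )
    return out
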
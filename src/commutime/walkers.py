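"""Monte-Carlo random walkers validating the closed-form commute times.

These walkers are a deliberately brute-force, independent check on the
Laplacian-pseudoinverse formulas: a walker at node i steps to neighbor k
with probability A_ik / D_ii and the number of steps to reach a target (and
return, for commute estimates) is averaged over many independent walks.

Higher-order chains probe memory effects: an order-2 walker never
immediately backtracks to the node it just left, and an order-3 walker also
avoids the node visited two steps ago (with backtracking allowed only when
no other neighbor exists, so the chain stays well-defined on leaves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import GraphOperators, StructuralConnectome, build_operators
from .metrics import commute_time, hitting_time

MAX_STEPS = 10_000_000  # hard cap per walk; capped walks are excluded and counted


@dataclass
class WalkEstimate:
    """Monte-Carlo estimate of a hitting or commute time for one pair."""

    source: int
    target: int
    order: int
    n_walks: int
    mean_steps: float
    stderr: float
    seed: int
    n_capped: int = 0


@njit(cache=True)
def _step(m_row: np.ndarray, u: float) -> int:
    """Sample a successor from one transition-matrix row given uniform u."""
    acc = 0.0
    last = -1
    for k in range(m_row.shape[0]):
        p = m_row[k]
        if p > 0.0:
            last = k
            acc += p
            if u < acc:
                return k
    return last  # guard against rounding: u landed past the accumulated sum


@njit(cache=True)
def _step_constrained(m_row: np.ndarray, forbid1: int, forbid2: int, u: float) -> int:
    """Sample a successor excluding up to two forbidden nodes, renormalized.

    If every neighbor is forbidden the constraint is dropped (deadlock
    escape: a leaf's walker may backtrack).
    """
    total = 0.0
    for k in range(m_row.shape[0]):
        if m_row[k] > 0.0 and k != forbid1 and k != forbid2:
            total += m_row[k]
    if total <= 0.0:
        return _step(m_row, u)
    acc = 0.0
    last = -1
    for k in range(m_row.shape[0]):
        p = m_row[k]
        if p > 0.0 and k != forbid1 and k != forbid2:
            last = k
            acc += p / total
            if u < acc:
                return k
    return last


@njit(cache=True)
def _walk_to(m: np.ndarray, start: int, target: int, order: int, max_steps: int) -> int:
    """Steps for one walk start→target under an order-1/2/3 chain; −1 if capped."""
    cur = start
    prev = -1
    prev2 = -1
    steps = 0
    while cur != target:
        if steps >= max_steps:
            return -1
        u = np.random.random()
        if order == 1:
            nxt = _step(m[cur], u)
        elif order == 2:
            nxt = _step_constrained(m[cur], prev, -1, u)
        else:
            nxt = _step_constrained(m[cur], prev, prev2, u)
        prev2 = prev
        prev = cur
        cur = nxt
        steps += 1
    return steps


@njit(cache=True)
def _simulate_pair(
    m: np.ndarray,
    source: int,
    target: int,
    n_walks: int,
    seed: int,
    order: int,
    round_trip: bool,
    max_steps: int,
) -> np.ndarray:
    """Step counts for n_walks independent (round-trip) walks; −1 marks capped."""
    np.random.seed(seed)
    out = np.empty(n_walks, dtype=np.float64)
    for w in range(n_walks):
        s1 = _walk_to(m, source, target, order, max_steps)
        if s1 < 0:
            out[w] = -1.0
            continue
        if round_trip:
            s2 = _walk_to(m, target, source, order, max_steps)
            out[w] = -1.0 if s2 < 0 else float(s1 + s2)
        else:
            out[w] = float(s1)
    return out


def _pair_seed(master_seed: int, source: int, target: int, order: int) -> int:
    """Independent 31-bit stream seed per (pair, order) from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(source), int(target), int(order)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _estimate(
    ops: GraphOperators,
    source: int,
    target: int,
    n_walks: int,
    seed: int,
    order: int,
    round_trip: bool,
) -> WalkEstimate:
    if source == target:
        raise ValueError("source and target must differ")
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    stream = _pair_seed(seed, source, target, order)
    steps = _simulate_pair(
        ops.transition, source, target, n_walks, stream, order, round_trip, MAX_STEPS
    )
    ok = steps[steps >= 0]
    n_capped = int((steps < 0).sum())
    if ok.size == 0:
        raise RuntimeError(
            f"all {n_walks} walks for pair ({source}, {target}) hit the step cap"
        )
    mean = float(ok.mean())
    stderr = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else float("nan")
    return WalkEstimate(
        source=source,
        target=target,
        order=order,
        n_walks=n_walks,
        mean_steps=mean,
        stderr=stderr,
        seed=seed,
        n_capped=n_capped,
    )


def simulate_hitting(
    ops: GraphOperators,
    source: int,
    target: int,
    n_walks: int,
    seed: int,
    order: int = 1,
) -> WalkEstimate:
    """Monte-Carlo estimate of the hitting time source→target."""
    return _estimate(ops, source, target, n_walks, seed, order, round_trip=False)


def simulate_commute(
    ops: GraphOperators,
    i: int,
    j: int,
    n_walks: int,
    seed: int,
    order: int = 1,
) -> WalkEstimate:
    """Monte-Carlo estimate of the commute time i→j→i (total round-trip steps)."""
    return _estimate(ops, i, j, n_walks, seed, order, round_trip=True)


def oracle_agreement(
    c: StructuralConnectome,
    n_walks: int,
    seed: int,
    order: int = 1,
    max_regions: int = 50,
    override_guard: bool = False,
):
    """Compare analytic commute times with simulated ones over all pairs.

    Returns a DataFrame with one row per unordered pair: analytic value,
    simulated mean, stderr, and the z-score (analytic − simulated)/stderr.
    The ``agreement`` attribute in ``df.attrs`` holds the fraction of pairs
    with |z| ≤ 3 (NaN-stderr pairs are flagged via the ``flagged`` column and
    excluded from the fraction).
    """
    import pandas as pd

    n = c.n_regions
    if n > max_regions and not override_guard:
        raise ValueError(
            f"N={n} exceeds the desk-scale guard ({max_regions}); "
            "pass override_guard=True to force"
        )
    ops = build_operators(c)
    analytic = commute_time(ops).values
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            est = simulate_commute(ops, i, j, n_walks, seed, order=order)
            diff = analytic[i, j] - est.mean_steps
            if est.stderr and np.isfinite(est.stderr):
                z = diff / est.stderr
            else:
                # zero/undefined spread: exact agreement is z=0, otherwise flagged
                z = 0.0 if abs(diff) < 1e-9 else np.nan
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "analytic": analytic[i, j],
                    "simulated": est.mean_steps,
                    "stderr": est.stderr,
                    "z": z,
                    "flagged": not np.isfinite(z),
                    "n_capped": est.n_capped,
                }
            )
    df = pd.DataFrame(rows)
    valid = df.loc[~df["flagged"], "z"]
    df.attrs["agreement"] = float((valid.abs() <= 3).mean()) if len(valid) else float("nan")
    df.attrs["seed"] = int(seed)
    df.attrs["order"] = int(order)
    return df
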
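"""Comparison machinery: pair vectors, Spearman/KS statistics, mode
truncation, metric comparison tables, and the end-to-end experiment runner.

Every structure–function question in this package reduces to the same
template: flatten two symmetric region-by-region matrices to vectors over
unordered region pairs (optionally restricted to one hemisphere), and rank
correlate them.  Principal-mode truncation reconstructs a matrix from the
leading eigenvectors of its eigendecomposition before the comparison, which
isolates the dominant coupling pattern from pairwise noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import StructuralConnectome, build_operators, write_matrix
from .metrics import MetricConfig, DEFAULT_CONFIG, compute_all_metrics

# Metrics whose raw orientation anti-correlates with FC; their sign is
# flipped for magnitude-comparable reporting (the additive inverse of
# commute time and of search information).
NEGATIVE_ORIENTED = frozenset({"commute_time", "mfpt_commute", "search_information"})


@dataclass(frozen=True)
class PairMask:
    """Selection of unordered region pairs entering a correlation."""

    mode: str = "all_pairs"  # all_pairs | intra_left | intra_right | custom
    custom_pairs: tuple[tuple[int, int], ...] = ()

    @classmethod
    def all_pairs(cls) -> "PairMask":
        return cls(mode="all_pairs")

    @classmethod
    def intra(cls, side: str) -> "PairMask":
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        return cls(mode=f"intra_{side}")

    def indices(self, n: int, hemisphere: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) index arrays in fixed row-major order."""
        iu, ju = np.triu_indices(n, k=1)
        if self.mode == "all_pairs":
            return iu, ju
        if self.mode in ("intra_left", "intra_right"):
            if hemisphere is None:
                raise ValueError(f"mask {self.mode} needs hemisphere labels")
            side = self.mode.removeprefix("intra_")
            hemi = np.asarray([h == side for h in hemisphere])
            keep = hemi[iu] & hemi[ju]
            return iu[keep], ju[keep]
        if self.mode == "custom":
            pairs = np.asarray(self.custom_pairs, dtype=int)
            if pairs.size and (pairs[:, 0] == pairs[:, 1]).any():
                raise ValueError("masks never include diagonal entries")
            return pairs[:, 0], pairs[:, 1]
        raise ValueError(f"unknown mask mode {self.mode!r}")


def pair_vector(
    m: np.ndarray,
    mask: PairMask = PairMask.all_pairs(),
    hemisphere: Sequence[str] | None = None,
) -> np.ndarray:
    """Flatten a symmetric matrix to its masked upper-triangle pair values."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got {m.shape}")
    finite = np.isfinite(m)
    both = finite & finite.T
    asym = np.abs(np.where(both, m - m.T, 0.0)).max()
    if asym > 1e-8 * max(np.abs(m[finite]).max(initial=1.0), 1.0):
        raise ValueError(f"pair_vector requires a symmetric matrix (|m-m.T| up to {asym:g})")
    iu, ju = mask.indices(m.shape[0], hemisphere)
    return m[iu, ju]


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value is two-sided from the large-n t approximation.  Constant
    input leaves ρ undefined: returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def ks_compare(d1: Sequence[float], d2: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic (max CDF gap) and asymptotic p."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.size < 2 or d2.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(d1, d2, method="asymp")
    return float(res.statistic), float(res.pvalue)


def top_mode(m: np.ndarray, k: int) -> np.ndarray:
    """Rank-k reconstruction from the largest algebraic eigenvalues.

    Σ_{r≤k} λ_r v_r v_rᵀ with eigenvalues sorted descending; each
    eigenvector's sign is fixed so its largest-magnitude component is
    positive, making the reconstruction deterministic.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[1] != n:
        raise ValueError("top_mode expects a square matrix")
    if np.abs(m - m.T).max() > 1e-8 * max(np.abs(m).max(), 1.0):
        raise ValueError("top_mode expects a symmetric matrix")
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    evals, evecs = np.linalg.eigh((m + m.T) / 2.0)
    order = np.argsort(evals)[::-1][:k]
    out = np.zeros_like(m)
    for r in order:
        v = evecs[:, r]
        lead = np.argmax(np.abs(v))
        if v[lead] < 0:
            v = -v
        out += evals[r] * np.outer(v, v)
    return out


@dataclass
class CorrelationReport:
    """Spearman ρ of one structural metric against one FC matrix."""

    metric_tag: str
    rho: float
    p_value: float
    n_pairs: int
    mask: PairMask
    fc_rank: str = "full"  # "full" or "top_k"
    metric_rank: str = "full"
    sign_flipped: bool = False
    metadata: dict = field(default_factory=dict)


def metric_comparison(
    c: StructuralConnectome,
    fc: np.ndarray,
    mask: PairMask = PairMask.all_pairs(),
    rank_settings: Sequence[tuple[str, str]] = (("full", "full"),),
    top_k: int = 2,
    config: MetricConfig = DEFAULT_CONFIG,
    metrics: dict | None = None,
) -> list[CorrelationReport]:
    """One correlation report per metric per (fc_rank, metric_rank) setting.

    The four compared structural metrics are raw connectivity, search
    information, communicability, and commute time.  For reporting, the
    additive inverse of commute time and search information is taken so all
    metric orientations are comparable; the flip is recorded per report.
    """
    fc = np.asarray(fc, dtype=float)
    if metrics is None:
        ops = build_operators(c)
        metrics = compute_all_metrics(c, ops, config)
    # Regions with undefined FC (constant time series) carry no functional
    # signal; drop them from the comparison, as one would drop missing-data
    # regions from an empirical FC matrix.
    n = fc.shape[0]
    bad = ~np.isfinite(fc)
    np.fill_diagonal(bad, False)
    valid = np.ones(n, dtype=bool)
    # greedily drop the region contributing the most undefined entries
    while True:
        counts = bad[np.ix_(valid, valid)].sum(axis=1)
        if counts.sum() == 0:
            break
        worst = np.flatnonzero(valid)[np.argmax(counts)]
        valid[worst] = False
        if valid.sum() < 3:
            raise ValueError("fewer than 3 regions have defined FC")
    vidx = np.flatnonzero(valid)
    fc_sub = fc[np.ix_(vidx, vidx)]
    hemi_sub = [c.hemisphere[i] for i in vidx]
    n_excluded = n - len(vidx)
    reports: list[CorrelationReport] = []
    for fc_rank, metric_rank in rank_settings:
        fc_used = top_mode(fc_sub, top_k) if fc_rank == "top_k" else fc_sub
        fc_vec = pair_vector(fc_used, mask, hemi_sub)
        for tag, metric in metrics.items():
            vals = metric.values[np.ix_(vidx, vidx)]
            flip = tag in NEGATIVE_ORIENTED
            if flip:
                vals = -vals
            if metric_rank == "top_k":
                vals = top_mode(vals, top_k)
            m_vec = pair_vector(vals, mask, hemi_sub)
            rho, p = spearman_correlation(m_vec, fc_vec)
            reports.append(
                CorrelationReport(
                    metric_tag=tag,
                    rho=rho,
                    p_value=p,
                    n_pairs=int(m_vec.size),
                    mask=mask,
                    fc_rank=fc_rank,
                    metric_rank=metric_rank,
                    sign_flipped=flip,
                    metadata={"top_k": top_k, "n_regions_excluded": n_excluded, **metric.metadata},
                )
            )
    return reports


def reports_to_frame(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric_tag": r.metric_tag,
                "rho": r.rho,
                "p_value": r.p_value,
                "n_pairs": r.n_pairs,
                "mask": r.mask.mode,
                "fc_rank": r.fc_rank,
                "metric_rank": r.metric_rank,
                "sign_flipped": r.sign_flipped,
            }
            for r in reports
        ]
    )


def run_experiment(config: dict, out_dir: str | Path) -> dict:
    """End-to-end pipeline: connectome → metrics → simulated FC → reports.

    ``config`` keys (all optional unless noted):

    - ``connectome``: either ``{"spec": {...ConnectomeSpec fields...}}`` or
      ``{"weights": path, "lengths": path, "sidecar": path}``
    - ``fc``: either ``{"ising": {...IsingConfig fields...}}`` or
      ``{"path": matrix file}``
    - ``replicates``: number of Ising replicates (default 1)
    - ``seed``: master seed (default 0)
    - ``masks``: list of mask modes (default ``["all_pairs"]``)
    - ``rank_settings``: list of [fc_rank, metric_rank] pairs
    - ``top_k``: truncation rank (default 2)

    Writes every intermediate matrix, per-replicate report tables, summary
    quartiles, and the resolved config to ``out_dir``; re-running with the
    same config reproduces every file bit-identically.
    """
    from .core import read_connectome
    from .ising import IsingConfig, simulate_fc
    from .synth import ConnectomeSpec, generate_connectome

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    replicates = int(config.get("replicates", 1))
    masks = [PairMask(mode=m) for m in config.get("masks", ["all_pairs"])]
    rank_settings = [tuple(rs) for rs in config.get("rank_settings", [["full", "full"]])]
    top_k = int(config.get("top_k", 2))

    conn_cfg = config.get("connectome", {"spec": {}})
    if "spec" in conn_cfg:
        spec = ConnectomeSpec(**{**conn_cfg["spec"], "seed": conn_cfg["spec"].get("seed", seed)})
        conn = generate_connectome(spec)
    else:
        conn = read_connectome(
            conn_cfg["weights"], conn_cfg.get("lengths"), conn_cfg.get("sidecar")
        )
    from .core import write_connectome

    write_connectome(conn, out_dir, stem="connectome")
    ops = build_operators(conn)
    metrics = compute_all_metrics(conn, ops)
    for tag, metric in metrics.items():
        write_matrix(metric, out_dir / f"metric_{tag}.tsv", conn.region_labels)

    fc_cfg = config.get("fc", {"ising": {}})
    fc_list: list[np.ndarray] = []
    if "path" in fc_cfg:
        from .core import read_matrix

        fc_values, _ = read_matrix(fc_cfg["path"])
        fc_list.append(fc_values)
    else:
        base = dict(fc_cfg.get("ising", {}))
        for rep in range(replicates):
            child = int(
                np.random.SeedSequence([seed, 0xFC, rep]).generate_state(1)[0] % (2**31 - 1)
            )
            cfg = IsingConfig(**{**base, "seed": child})
            fc = simulate_fc(conn, cfg)
            fc_list.append(fc.values)
            write_matrix(fc.values, out_dir / f"fc_rep{rep:03d}.tsv", conn.region_labels)

    all_rows = []
    for rep, fc_values in enumerate(fc_list):
        for mask in masks:
            reports = metric_comparison(
                conn, fc_values, mask, rank_settings, top_k=top_k, metrics=metrics
            )
            frame = reports_to_frame(reports)
            frame.insert(0, "replicate", rep)
            all_rows.append(frame)
    table = pd.concat(all_rows, ignore_index=True)
    table.to_csv(out_dir / "correlation_reports.tsv", sep="\t", index=False)

    summary = (
        table.groupby(["metric_tag", "mask", "fc_rank", "metric_rank"])["rho"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q25", 0.5: "median", 0.75: "q75"})
        .reset_index()
    )
    summary.to_csv(out_dir / "summary_quartiles.tsv", sep="\t", index=False)
    with (out_dir / "experiment_config.yaml").open("w") as fh:
        yaml.safe_dump({**config, "seed": seed, "replicates": replicates}, fh, sort_keys=True)
    return {"reports": table, "summary": summary, "connectome": conn}
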
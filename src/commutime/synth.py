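"""Synthetic structural connectomes and the perturbations used in analysis.

Real dMRI-derived connectomes (tract-count matrices under an ~84-region
cortical/subcortical parcellation) are sparse, symmetric, nonnegative
integer matrices with heavy-tailed weights and a clear two-hemisphere block
structure: connectivity within a hemisphere is denser and stronger than
between hemispheres.  The generator emulates exactly that statistical
shape — it makes no attempt to match any particular cohort's degree or
weight distribution quantitatively.

Perturbations mirror the analysis experiments: a weight-shuffling null that
destroys topology while keeping the weight multiset, and homotopic vs
budget-matched random tract addition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConnectomeError, StructuralConnectome, graph_components


@dataclass(frozen=True)
class ConnectomeSpec:
    """Parameters of the synthetic connectome ensemble.

    Defaults emulate a Desikan-Killiany-scale (84-region) tract-count
    matrix: ~35% of within-hemisphere pairs connected versus ~8% of
    between-hemisphere pairs, log-normal streamline counts with a heavy
    tail (median ≈ e³ ≈ 20 tracts, σ_log = 2 so counts span roughly four
    decades, 1 to ~10⁴, as deterministic tractography produces), and tract
    lengths around 40 mm within a hemisphere with longer inter-hemispheric
    tracts.
    """

    n_regions: int = 84
    intra_density: float = 0.35
    inter_density: float = 0.08
    weight_log_mean: float = 3.0
    weight_log_sd: float = 2.0
    inter_weight_log_shift: float = -1.0  # inter-hemisphere weights are weaker
    homotopic_weight: int = 0
    length_scale: float = 40.0
    length_sd: float = 10.0
    inter_length_factor: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_regions % 2:
            raise ConnectomeError("n_regions must be an even count >= 2")
        if not (0.0 < self.intra_density <= 1.0):
            raise ConnectomeError("intra_density must be in (0, 1]")
        if not (0.0 <= self.inter_density <= 1.0):
            raise ConnectomeError("inter_density must be in [0, 1]")
        if self.inter_density > self.intra_density:
            raise ConnectomeError("inter_density must not exceed intra_density")
        if self.inter_density == 0 and self.homotopic_weight <= 0:
            raise ConnectomeError(
                "inter_density=0 with no homotopic tracts disconnects the hemispheres"
            )
        if self.homotopic_weight < 0:
            raise ConnectomeError("homotopic_weight must be >= 0")


def _default_labels(n: int) -> tuple[list[str], list[str]]:
    half = n // 2
    labels = [f"L.region{i:02d}" for i in range(half)] + [
        f"R.region{i:02d}" for i in range(half)
    ]
    hemisphere = ["left"] * half + ["right"] * half
    return labels, hemisphere


def generate_connectome(spec: ConnectomeSpec) -> StructuralConnectome:
    """Draw one synthetic connectome; fully reproducible from ``spec.seed``.

    Weights are integer-rounded log-normal tract counts (≥ 1 on the support)
    with inter-hemisphere magnitudes shifted down so the intra > inter
    mean-weight ordering holds by construction.  If the sampled support is
    disconnected, deterministic bridges (median-weight edges from the first
    node of each stray component to node 0) restore connectivity.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    half = n // 2
    hemi_idx = np.array([0] * half + [1] * half)
    intra_block = hemi_idx[:, None] == hemi_idx[None, :]

    iu, ju = np.triu_indices(n, k=1)
    intra_pair = intra_block[iu, ju]
    density = np.where(intra_pair, spec.intra_density, spec.inter_density)
    present = rng.random(iu.size) < density
    mu = np.where(
        intra_pair, spec.weight_log_mean, spec.weight_log_mean + spec.inter_weight_log_shift
    )
    raw = rng.lognormal(mean=0.0, sigma=spec.weight_log_sd, size=iu.size) * np.exp(mu)
    w_pairs = np.where(present, np.maximum(np.rint(raw), 1.0), 0.0)

    weights = np.zeros((n, n))
    weights[iu, ju] = w_pairs
    weights += weights.T

    homotopic_pairs = [(i, i + half) for i in range(half)]
    if spec.homotopic_weight > 0:
        for i, j in homotopic_pairs:
            weights[i, j] += spec.homotopic_weight
            weights[j, i] += spec.homotopic_weight

    # deterministic bridging to guarantee a single component
    comps = graph_components(weights)
    if len(comps) > 1:
        comps = sorted(comps, key=min)
        anchor = min(comps[0])
        bridge_w = max(np.median(weights[weights > 0]), 1.0) if (weights > 0).any() else 1.0
        for comp in comps[1:]:
            j = min(comp)
            weights[anchor, j] += np.rint(bridge_w)
            weights[j, anchor] += np.rint(bridge_w)

    # tract lengths on the same support; inter-hemisphere tracts run longer
    lengths = np.zeros((n, n))
    support_i, support_j = np.nonzero(np.triu(weights, k=1))
    base = rng.normal(spec.length_scale, spec.length_sd, size=support_i.size)
    factor = np.where(intra_block[support_i, support_j], 1.0, spec.inter_length_factor)
    vals = np.maximum(base * factor, 1.0)
    lengths[support_i, support_j] = vals
    lengths += lengths.T

    labels, hemisphere = _default_labels(n)
    return StructuralConnectome(
        region_labels=labels,
        hemisphere=hemisphere,
        weights=weights,
        lengths=lengths,
        homotopic_pairs=homotopic_pairs,
    )


def shuffle_null(c: StructuralConnectome, seed: int, max_tries: int = 1000) -> StructuralConnectome:
    """Topology-destroying null: permute the upper-triangle weights.

    The weight multiset, symmetry, and zero diagonal are preserved; the
    permutation is resampled (deterministically from ``seed``) until the
    shuffled graph is connected.  Lengths are dropped (they no longer
    correspond to any tract geometry).
    """
    rng = np.random.default_rng(seed)
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    vals = c.weights[iu, ju]
    for _ in range(max_tries):
        perm = rng.permutation(vals.size)
        shuffled = np.zeros((n, n))
        shuffled[iu, ju] = vals[perm]
        shuffled += shuffled.T
        if len(graph_components(shuffled)) == 1:
            return StructuralConnectome(
                region_labels=list(c.region_labels),
                hemisphere=list(c.hemisphere),
                weights=shuffled,
                lengths=None,
                homotopic_pairs=list(c.homotopic_pairs),
            )
    raise ConnectomeError(f"no connected shuffle found in {max_tries} tries")


def add_homotopic_tracts(c: StructuralConnectome, k: int) -> StructuralConnectome:
    """Add ``k`` tracts to every homotopic (left, right-twin) pair."""
    if k < 0:
        raise ConnectomeError("tract count k must be >= 0")
    if not c.homotopic_pairs:
        raise ConnectomeError("connectome has no homotopic pair map")
    out = c.copy()
    if k == 0:
        return out
    for i, j in c.homotopic_pairs:
        out.weights[i, j] += k
        out.weights[j, i] += k
    if out.lengths is not None:
        # new tracts need a geometry: give previously absent homotopic edges
        # the typical inter-hemispheric length so the support stays consistent
        nonzero = out.lengths[out.lengths > 0]
        fill = float(np.median(nonzero)) if nonzero.size else 1.0
        for i, j in c.homotopic_pairs:
            if out.lengths[i, j] == 0:
                out.lengths[i, j] = fill
                out.lengths[j, i] = fill
    return out


def add_random_tracts(c: StructuralConnectome, k: int, seed: int) -> StructuralConnectome:
    """Budget-matched control: add ``k`` tracts to random non-homotopic pairs.

    The same number of pair entries as the homotopic map receive +k, at
    uniformly random off-diagonal non-homotopic positions.
    """
    if k < 0:
        raise ConnectomeError("tract count k must be >= 0")
    if not c.homotopic_pairs:
        raise ConnectomeError("connectome has no homotopic pair map")
    out = c.copy()
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    homotopic = {tuple(sorted(p)) for p in c.homotopic_pairs}
    eligible = [idx for idx, (i, j) in enumerate(zip(iu, ju)) if (i, j) not in homotopic]
    n_add = len(c.homotopic_pairs)
    if n_add > len(eligible):
        raise ConnectomeError(
            f"cannot place {n_add} additions among {len(eligible)} eligible pairs"
        )
    chosen = rng.choice(len(eligible), size=n_add, replace=False)
    fill = 1.0
    if out.lengths is not None:
        nonzero = out.lengths[out.lengths > 0]
        fill = float(np.median(nonzero)) if nonzero.size else 1.0
    for idx in chosen:
        i, j = int(iu[eligible[idx]]), int(ju[eligible[idx]])
        out.weights[i, j] += k
        out.weights[j, i] += k
        if out.lengths is not None and out.lengths[i, j] == 0:
            out.lengths[i, j] = fill
            out.lengths[j, i] = fill
    return out
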
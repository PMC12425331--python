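"""Core domain types, graph operators, and matrix file I/O.

A structural connectome is a weighted undirected graph whose nodes are brain
regions and whose edge weights are white-matter streamline counts from
diffusion tractography.  All downstream machinery (random-walk metrics, Ising
simulation, correlation analysis) consumes the operators derived here: the
degree matrix ``D``, the graph Laplacian ``Γ = D − A``, its Moore–Penrose
pseudoinverse ``Γ⁺``, and the row-stochastic Markov transition matrix
``M = D⁻¹ A``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8

AdjacencyVariant = Literal["density", "binary", "length"]


class ConnectomeError(ValueError):
    """Base class for connectome validation failures."""


class NonSquareMatrixError(ConnectomeError):
    """Input table is not square."""


class AsymmetricMatrixError(ConnectomeError):
    """Adjacency asymmetric beyond the repair tolerance."""


class NegativeWeightError(ConnectomeError):
    """Adjacency contains negative entries."""


class NaNEntryError(ConnectomeError):
    """Adjacency contains NaN entries."""


class DisconnectedGraphError(ConnectomeError):
    """Graph has more than one connected component.

    Commute time is undefined across components, so operator construction
    refuses disconnected input instead of silently working per component.
    """

    def __init__(self, components: Sequence[Sequence[int]]):
        self.components = [list(c) for c in components]
        sizes = ", ".join(str(len(c)) for c in self.components)
        super().__init__(
            f"graph has {len(self.components)} connected components "
            f"(sizes: {sizes}); commute time is undefined across components"
        )


def _validate_adjacency(weights: np.ndarray, *, what: str = "weights") -> np.ndarray:
    """Validate and canonicalize a weight matrix (symmetrize, strip diagonal)."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise NonSquareMatrixError(f"{what} matrix must be square, got shape {weights.shape}")
    if weights.shape[0] < 2:
        raise ConnectomeError(f"need at least 2 regions, got {weights.shape[0]}")
    if np.isnan(weights).any():
        raise NaNEntryError(f"{what} matrix contains NaN entries")
    if (weights < 0).any():
        raise NegativeWeightError(f"{what} matrix contains negative entries")
    asym = np.abs(weights - weights.T).max()
    scale = max(np.abs(weights).max(), 1.0)
    if asym > SYMMETRY_TOL * scale:
        raise AsymmetricMatrixError(
            f"{what} matrix asymmetric beyond tolerance: max |A - A.T| = {asym:g}"
        )
    if asym > 0:
        weights = (weights + weights.T) / 2.0
    if np.any(np.diag(weights) != 0):
        logger.warning("stripping nonzero diagonal (self-loops are removed from consideration)")
        weights = weights.copy()
        np.fill_diagonal(weights, 0.0)
    return weights


@dataclass
class StructuralConnectome:
    """Weighted symmetric adjacency of streamline counts, plus metadata.

    Parameters
    ----------
    region_labels : list of str
        One label per region, length N.
    hemisphere : list of str
        Per-region hemisphere assignment, each ``"left"`` or ``"right"``.
    weights : (N, N) ndarray
        Symmetric nonnegative streamline counts, zero diagonal.
    lengths : (N, N) ndarray, optional
        Mean tract lengths (mm) on the same sparsity pattern as ``weights``.
    homotopic_pairs : list of (int, int)
        Index pairs linking each left region to its right-hemisphere twin.
    """

    region_labels: list[str]
    hemisphere: list[str]
    weights: np.ndarray
    lengths: np.ndarray | None = None
    homotopic_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = _validate_adjacency(self.weights)
        n = self.weights.shape[0]
        if len(self.region_labels) != n:
            raise ConnectomeError(
                f"{len(self.region_labels)} labels for {n} regions"
            )
        if len(self.hemisphere) != n:
            raise ConnectomeError(
                f"{len(self.hemisphere)} hemisphere labels for {n} regions"
            )
        bad = sorted({h for h in self.hemisphere} - {"left", "right"})
        if bad:
            raise ConnectomeError(f"hemisphere labels must be 'left'/'right', got {bad}")
        if self.lengths is not None:
            self.lengths = _validate_adjacency(self.lengths, what="lengths")
            if self.lengths.shape != self.weights.shape:
                raise ConnectomeError("lengths shape does not match weights")
            if ((self.lengths > 0) != (self.weights > 0)).any():
                raise ConnectomeError("lengths must share the sparsity pattern of weights")
        self.homotopic_pairs = [(int(i), int(j)) for i, j in self.homotopic_pairs]
        for i, j in self.homotopic_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ConnectomeError(f"homotopic pair ({i}, {j}) out of range for N={n}")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "StructuralConnectome":
        return StructuralConnectome(
            region_labels=list(self.region_labels),
            hemisphere=list(self.hemisphere),
            weights=self.weights.copy(),
            lengths=None if self.lengths is None else self.lengths.copy(),
            homotopic_pairs=list(self.homotopic_pairs),
        )


@dataclass
class GraphOperators:
    """Markov/graph operators derived from one adjacency matrix.

    ``degree`` is the diagonal matrix D with D_ii the i-th row sum of A,
    ``laplacian`` is Γ = D − A, ``laplacian_pinv`` its Moore–Penrose
    pseudoinverse Γ⁺, and ``transition`` the row-stochastic M = D⁻¹A.
    """

    adjacency: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray
    laplacian_pinv: np.ndarray
    transition: np.ndarray
    variant: str = "density"

    @property
    def degree_vector(self) -> np.ndarray:
        return np.diag(self.degree)

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]


def graph_components(adjacency: np.ndarray) -> list[list[int]]:
    """Connected components of a (symmetric) adjacency, as index lists."""
    n_comp, labels = connected_components(csr_matrix(adjacency > 0), directed=False)
    return [list(np.flatnonzero(labels == c)) for c in range(n_comp)]


def laplacian_pinv(laplacian: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Moore–Penrose pseudoinverse of a graph Laplacian via eigendecomposition.

    The Laplacian of a connected graph has exactly one zero eigenvalue (the
    constant vector); eigenvalues below ``rtol`` times the largest are treated
    as that null space and dropped, which controls the null space explicitly
    instead of relying on generic SVD cutoffs.
    """
    evals, evecs = np.linalg.eigh(laplacian)
    cutoff = rtol * evals.max()
    inv = np.where(evals > cutoff, 1.0 / np.where(evals > cutoff, evals, 1.0), 0.0)
    return (evecs * inv) @ evecs.T


def build_operators(
    c: StructuralConnectome,
    variant: AdjacencyVariant = "density",
    *,
    invert_lengths: bool = False,
) -> GraphOperators:
    """Construct D, Γ, Γ⁺ and M from a connectome under an adjacency variant.

    Parameters
    ----------
    c : StructuralConnectome
    variant : {"density", "binary", "length"}
        ``density`` uses raw streamline counts, ``binary`` the 0/1 support,
        ``length`` the tract-length values as edge weights.
    invert_lengths : bool
        With ``variant="length"``, use 1/length instead of length as the
        weight (shorter tracts couple more strongly).

    Raises
    ------
    DisconnectedGraphError
        If the variant adjacency has more than one connected component.
    """
    if variant == "density":
        a = c.weights.astype(float)
    elif variant == "binary":
        a = (c.weights > 0).astype(float)
    elif variant == "length":
        if c.lengths is None:
            raise ConnectomeError("variant='length' requires a lengths matrix")
        a = c.lengths.astype(float)
        if invert_lengths:
            a = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown variant {variant!r}")

    comps = graph_components(a)
    if len(comps) != 1:
        raise DisconnectedGraphError(comps)

    d = a.sum(axis=1)
    degree = np.diag(d)
    lap = degree - a
    pinv = laplacian_pinv(lap)
    transition = a / d[:, None]
    return GraphOperators(
        adjacency=a,
        degree=degree,
        laplacian=lap,
        laplacian_pinv=pinv,
        transition=transition,
        variant=variant,
    )


METRIC_TAGS = (
    "commute_time",
    "hitting_time",
    "mfpt_commute",
    "communicability",
    "search_information",
    "connectivity",
    "resistance",
)

# Tags whose matrices are symmetric; hitting time and raw search information
# are asymmetric until explicitly symmetrized.
_SYMMETRIC_TAGS = frozenset(METRIC_TAGS) - {"hitting_time", "search_information"}
_ZERO_DIAG_TAGS = frozenset({"commute_time", "hitting_time", "mfpt_commute", "resistance"})


@dataclass
class PairwiseMetric:
    """A region-by-region metric matrix with its metric tag."""

    values: np.ndarray
    metric_tag: str
    symmetric: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric_tag not in METRIC_TAGS:
            raise ValueError(f"unknown metric tag {self.metric_tag!r}")
        if self.metric_tag in _SYMMETRIC_TAGS and not self.symmetric:
            raise ValueError(f"{self.metric_tag} must be symmetric")
        if self.symmetric:
            asym = np.abs(self.values - self.values.T).max()
            scale = max(np.abs(self.values).max(), 1.0)
            if asym > 1e-9 * scale:
                raise ValueError(f"{self.metric_tag} marked symmetric but |m-m.T|={asym:g}")
        if self.metric_tag in _ZERO_DIAG_TAGS and np.abs(np.diag(self.values)).max() > 1e-9:
            raise ValueError(f"{self.metric_tag} must have zero diagonal")


# ---------------------------------------------------------------------------
# File I/O: TSV matrices with region-label header/index, YAML sidecars.
# ---------------------------------------------------------------------------


def write_matrix(
    values: np.ndarray | PairwiseMetric,
    path: str | Path,
    region_labels: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a matrix as TSV with region labels; bit-exact round-trip.

    Floats are written with Python's shortest ``repr``, which round-trips
    exactly through ``float()``.  Optional metadata is written to a YAML
    sidecar ``<path>.meta.yaml``.
    """
    meta = dict(metadata or {})
    if isinstance(values, PairwiseMetric):
        meta.setdefault("metric_tag", values.metric_tag)
        meta.setdefault("symmetric", bool(values.symmetric))
        meta.update(values.metadata)
        values = values.values
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise NonSquareMatrixError(f"expected a square matrix, got shape {values.shape}")
    if values.shape[0] < 2:
        raise ConnectomeError("refusing to write a matrix with fewer than 2 regions")
    n = values.shape[0]
    if region_labels is None:
        region_labels = [f"region_{i}" for i in range(n)]
    if len(region_labels) != n:
        raise ConnectomeError(f"{len(region_labels)} labels for {n} regions")

    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["region", *region_labels]) + "\n")
        for label, row in zip(region_labels, values):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    if meta:
        with Path(str(path) + ".meta.yaml").open("w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled TSV matrix; returns (values, region_labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != labels:
        raise ConnectomeError(f"row labels do not match column labels in {path}")
    return df.to_numpy(dtype=float), labels


def write_connectome(c: StructuralConnectome, out_dir: str | Path, stem: str = "connectome") -> None:
    """Write weights, optional lengths, and the hemisphere/homotopic sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_matrix(c.weights, out_dir / f"{stem}_weights.tsv", c.region_labels)
    if c.lengths is not None:
        write_matrix(c.lengths, out_dir / f"{stem}_lengths.tsv", c.region_labels)
    sidecar = {
        "hemisphere": list(c.hemisphere),
        "homotopic_pairs": [[int(i), int(j)] for i, j in c.homotopic_pairs],
    }
    with (out_dir / f"{stem}_regions.yaml").open("w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_connectome(
    path: str | Path,
    lengths_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
) -> StructuralConnectome:
    """Read a connectome from a TSV weights matrix plus optional companions.

    Adjacency asymmetric within 1e-8 (relative) is repaired by averaging;
    larger asymmetry, negative or NaN entries, and non-square tables each
    raise a distinct :class:`ConnectomeError` subclass.
    """
    weights, labels = read_matrix(path)
    lengths = None
    if lengths_path is not None:
        lengths, llabels = read_matrix(lengths_path)
        if llabels != labels:
            raise ConnectomeError("lengths file labels do not match weights file labels")
    hemisphere: list[str] | None = None
    homotopic: list[tuple[int, int]] = []
    if sidecar_path is not None:
        with Path(sidecar_path).open() as fh:
            sidecar = yaml.safe_load(fh)
        hemisphere = list(sidecar.get("hemisphere", []))
        homotopic = [tuple(p) for p in sidecar.get("homotopic_pairs", [])]
    if hemisphere is None:
        # Without a sidecar, assume the conventional ordering: first half
        # left hemisphere, second half right.
        n = len(labels)
        hemisphere = ["left"] * (n - n // 2) + ["right"] * (n // 2)
    return StructuralConnectome(
        region_labels=labels,
        hemisphere=hemisphere,
        weights=weights,
        lengths=lengths,
        homotopic_pairs=homotopic,
    )
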
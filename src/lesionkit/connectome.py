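"""Structural connectome container, I/O, weighted Jaccard similarity and lesions.

The structural connectome (SC) is a weighted, symmetric, zero-diagonal
region-by-region matrix of anatomical coupling strengths, here with a
bi-hemispheric labelling (34 regions per hemisphere in the standard
Desikan-Killiany-style cortical parcellation, though any even split works).

Structurally similar areas (SSAs) of a prospective lesion site are the
top-fraction regions ranked by weighted Jaccard similarity of their
connectivity profiles; a virtual lesion zeroes one region's row and column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "ConnectomeFormatError",
    "SimilarityProfile",
    "AreaSet",
    "read_connectome",
    "write_connectome",
    "jaccard_profile",
    "jaccard_matrix",
    "select_ssa",
    "apply_lesion",
    "nodal_strength",
    "nodal_degree",
    "top_n_count",
]

_SYMMETRY_TOL = 1e-9


class ConnectomeFormatError(ValueError):
    """Raised for malformed connectivity matrices or label mismatches."""


@dataclass
class Connectome:
    """Weighted structural connectivity with region and hemisphere labels.

    Parameters
    ----------
    weights
        Square, symmetric, non-negative matrix with zero diagonal
        (dimensionless edge strengths C_ij).
    region_labels
        One name per region, in matrix order.
    hemisphere
        Per-region tag, ``"L"`` or ``"R"``. If omitted, the first half of
        the regions is labelled L and the second half R.
    """

    weights: np.ndarray
    region_labels: list[str]
    hemisphere: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeFormatError(f"weights must be square, got shape {w.shape}")
        n = w.shape[0]
        if len(self.region_labels) != n:
            raise ConnectomeFormatError(
                f"{len(self.region_labels)} labels for a {n}x{n} matrix"
            )
        if np.any(w < 0):
            raise ConnectomeFormatError("negative entries in connectivity matrix")
        if not np.allclose(w, w.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ConnectomeFormatError("connectivity matrix is not symmetric")
        if np.any(np.diag(w) != 0.0):
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        self.weights = w
        if not self.hemisphere:
            half = n // 2
            self.hemisphere = ["L"] * half + ["R"] * (n - half)
        if len(self.hemisphere) != n:
            raise ConnectomeFormatError("hemisphere tags do not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.region_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None

    def hemisphere_indices(self, tag: str) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemisphere) if h == tag], dtype=int)


@dataclass
class SimilarityProfile:
    """Weighted Jaccard similarity of every region to one reference region.

    ``jc[reference]`` is 1 by convention and is excluded from any ranking.
    """

    reference_region: int
    jc: np.ndarray


@dataclass
class AreaSet:
    """A ranked top-fraction selection of regions (SSA, DSA or their overlap)."""

    members: frozenset[int]
    fraction: float
    source: str
    ranked: tuple[int, ...] = ()


def top_n_count(fraction: float, n_regions: int) -> int:
    """Number of areas in a top-``fraction`` selection: round(fraction * n)."""
    return int(np.floor(fraction * n_regions + 0.5))


# ---------------------------------------------------------------------------
# I/O: plain-text TSV matrices with labels as header row and index column.
# ---------------------------------------------------------------------------

def write_connectome(c: Connectome, path) -> None:
    df = pd.DataFrame(c.weights, index=c.region_labels, columns=c.region_labels)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_connectome(path, hemisphere: list[str] | None = None) -> Connectome:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    labels = [str(x) for x in df.columns]
    row_labels = [str(x) for x in df.index]
    if labels != row_labels:
        raise ConnectomeFormatError("row and column labels differ")
    w = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(w)):
        raise ConnectomeFormatError("non-finite entries in connectivity matrix")
    return Connectome(w, labels, hemisphere or [])


# ---------------------------------------------------------------------------
# Weighted Jaccard similarity
# ---------------------------------------------------------------------------

def jaccard_profile(c: Connectome, reference: int) -> SimilarityProfile:
    """Weighted Jaccard coefficient of every region's profile to ``reference``.

    For regions A (reference) and B, JC = sum_k min(C_Ak, C_Bk) /
    sum_k max(C_Ak, C_Bk) over third parties k not in {A, B}: the ratio of
    common to total neighbour weight, the weighted form of |A∩B| / |A∪B|.
    """
    w = c.weights
    n = c.n_regions
    a = w[reference]
    jc = np.empty(n, dtype=float)
    degenerate = False
    for b_idx in range(n):
        if b_idx == reference:
            jc[b_idx] = 1.0
            continue
        mask = np.ones(n, dtype=bool)
        mask[reference] = False
        mask[b_idx] = False
        b = w[b_idx]
        num = np.minimum(a[mask], b[mask]).sum()
        den = np.maximum(a[mask], b[mask]).sum()
        if den == 0.0:
            jc[b_idx] = 0.0
            degenerate = True
        else:
            jc[b_idx] = num / den
    if degenerate:
        warnings.warn(
            f"region {reference} has degenerate (zero-weight) neighbourhood pairs; "
            "their JC is set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimilarityProfile(reference_region=reference, jc=jc)


def jaccard_matrix(c: Connectome) -> np.ndarray:
    """Full region-by-region weighted Jaccard matrix (unit diagonal)."""
    n = c.n_regions
    out = np.empty((n, n), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            out[i] = jaccard_profile(c, i).jc
    return out


def _ranked_top(values: np.ndarray, exclude: int | None, n_top: int) -> tuple[int, ...]:
    """Indices of the ``n_top`` largest values, ties broken by ascending index."""
    n = len(values)
    candidates = [i for i in range(n) if i != exclude]
    candidates.sort(key=lambda i: (-values[i], i))
    return tuple(candidates[:n_top])


def select_ssa(profile: SimilarityProfile, fraction: float = 0.25) -> AreaSet:
    """Structurally similar areas: top-fraction regions by JC to the reference.

    N = round(fraction x n_regions); the reference (prospective lesion site)
    is excluded from candidacy. Ties are broken by ascending region index.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(profile.jc)
    n_top = min(top_n_count(fraction, n), n - 1)
    ranked = _ranked_top(profile.jc, profile.reference_region, n_top)
    return AreaSet(members=frozenset(ranked), fraction=fraction, source="SSA", ranked=ranked)


# ---------------------------------------------------------------------------
# Virtual lesion and nodal measures
# ---------------------------------------------------------------------------

def apply_lesion(c: Connectome, node: int) -> Connectome:
    """Virtual focal lesion: zero all connections to and from ``node``.

    All other entries are returned bitwise unchanged.
    """
    n = c.n_regions
    if not 0 <= node < n:
        raise IndexError(f"lesion node {node} out of range for {n} regions")
    w = c.weights.copy()
    w[node, :] = 0.0
    w[:, node] = 0.0
    return Connectome(w, list(c.region_labels), list(c.hemisphere))


def nodal_strength(c: Connectome) -> np.ndarray:
    """Weighted degree (row sums) per region."""
    return c.weights.sum(axis=1)


def nodal_degree(c: Connectome) -> np.ndarray:
    """Count of non-zero connections per region."""
    return np.count_nonzero(c.weights, axis=1)
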
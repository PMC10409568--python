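"""Synthetic structural-connectome cohorts.

Generates cohorts of bi-hemispheric, modular, weighted connectomes with the
statistical features the virtual-lesion analysis relies on: heavy-tailed
(log-normal) edge weights as produced by tractography, community structure
mirrored across hemispheres, homotopic inter-hemispheric links that are each
region's strongest callosal edge, and multiplicative subject-level
variability around a shared group skeleton. Optionally a set of "twin"
regions with near-identical connectivity profiles to a designated seed
region can be planted, giving a ground-truth target for similarity-based
recovery analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .connectome import Connectome, write_connectome

__all__ = ["CohortSpec", "generate_connectome", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate a resting-state cohort of 49 subjects parcellated into
    34 cortical regions per hemisphere. ``n_modules`` counts communities per
    hemisphere, mirrored left/right. Densities are edge probabilities;
    weights are log-normal with the given location/scale of log-weight;
    ``subject_jitter`` is the standard deviation of multiplicative
    log-normal edge noise applied per subject around the group skeleton.
    ``planted_twin_size`` > 0 plants that many regions whose profiles copy
    the twin-seed region (region 0).

    Regions are embedded on a ring per hemisphere (mirrored left/right) and
    within-hemisphere weights decay exponentially with ring distance
    (e-folding ``distance_decay`` in index units, 0 disables it), emulating
    the exponential distance rule of cortical wiring; this is what couples
    profile similarity (shared neighbourhoods) to direct connection
    strength in real connectomes.

    Inter-hemispheric (callosal) edges mirror the ipsilateral topography:
    the edge between left-i and right-j is ``callosal_mirror`` times the
    mean of the two hemispheres' i-j weights, retained with probability
    ``cross_hemisphere_density``. This gives homotopic pairs the similar
    connectivity profiles they have in real connectomes (the basis of
    contralesional-homologue recruitment), on top of the homotopic edge
    itself being each region's strongest callosal link.
    """

    n_subjects: int = 49
    n_regions: int = 68
    n_per_hemisphere: int = 34
    n_modules: int = 4
    intra_module_density: float = 0.7
    inter_module_density: float = 0.15
    cross_hemisphere_density: float = 0.5
    callosal_mirror: float = 0.4
    distance_decay: float = 6.0
    homotopic_strength: float = 1.0
    weight_log_location: float = 0.0
    weight_log_scale: float = 1.0
    subject_jitter: float = 0.1
    planted_twin_size: int = 0
    twin_seed_region: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions != 2 * self.n_per_hemisphere:
            raise ValueError("n_regions must equal 2 x n_per_hemisphere")
        if self.n_subjects < 1 or self.n_modules < 1:
            raise ValueError("n_subjects and n_modules must be positive")
        for name in ("intra_module_density", "inter_module_density",
                     "cross_hemisphere_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.homotopic_strength <= 0 or self.weight_log_scale <= 0:
            raise ValueError("scales must be > 0")
        if self.callosal_mirror < 0:
            raise ValueError("callosal_mirror must be >= 0")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be >= 0")
        if self.planted_twin_size < 0 or self.planted_twin_size >= self.n_per_hemisphere:
            raise ValueError("planted_twin_size must be in [0, n_per_hemisphere)")

    def module_assignment(self) -> np.ndarray:
        """Per-region module id, mirrored across hemispheres."""
        per_mod = np.array_split(np.arange(self.n_per_hemisphere), self.n_modules)
        labels = np.empty(self.n_regions, dtype=int)
        for m, idx in enumerate(per_mod):
            labels[idx] = m
            labels[idx + self.n_per_hemisphere] = m
        return labels

    def region_labels(self) -> list[str]:
        h = self.n_per_hemisphere
        return [f"L{i:02d}" for i in range(h)] + [f"R{i:02d}" for i in range(h)]


def _hemisphere_block(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """One hemisphere's intra-hemispheric weight matrix."""
    h = spec.n_per_hemisphere
    modules = spec.module_assignment()[:h]
    iu, ju = np.triu_indices(h, k=1)
    p = np.where(modules[iu] == modules[ju],
                 spec.intra_module_density, spec.inter_module_density)
    present = rng.random(iu.size) < p
    raw = rng.lognormal(spec.weight_log_location, spec.weight_log_scale,
                        size=iu.size)
    if spec.distance_decay > 0:
        d = np.abs(iu - ju)
        d = np.minimum(d, h - d)        # ring distance
        raw = raw * np.exp(-d / spec.distance_decay)
    block = np.zeros((h, h))
    block[iu, ju] = np.where(present, raw, 0.0)
    return block + block.T


def _group_skeleton(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Shared (pre-jitter) weight matrix of the cohort."""
    h = spec.n_per_hemisphere
    left = _hemisphere_block(spec, rng)
    right = _hemisphere_block(spec, rng)

    # Callosal block mirrors the ipsilateral topography (attenuated and
    # sparsified), so homotopic pairs share third-party neighbourhoods.
    base = 0.5 * (left + right)
    jitter = rng.lognormal(0.0, 0.3, size=(h, h))
    keep = rng.random((h, h)) < spec.cross_hemisphere_density
    cross = spec.callosal_mirror * base * jitter * keep

    # Homotopic edges always exist and carry their own weight scale ...
    homo = rng.lognormal(np.log(spec.homotopic_strength)
                         + spec.weight_log_location,
                         spec.weight_log_scale, size=h)
    np.fill_diagonal(cross, homo)
    # ... and are enforced to be each region's strongest callosal edge.
    for i in range(h):
        off_row = np.delete(cross[i], i).max(initial=0.0)
        off_col = np.delete(cross[:, i], i).max(initial=0.0)
        floor = 1.05 * max(off_row, off_col)
        if cross[i, i] <= floor:
            cross[i, i] = floor if floor > 0 else spec.homotopic_strength

    w = np.zeros((2 * h, 2 * h))
    w[:h, :h] = left
    w[h:, h:] = right
    w[:h, h:] = cross
    w[h:, :h] = cross.T
    return w


def _plant_twins(spec: CohortSpec, w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Overwrite twin rows/columns with near-copies of the seed's profile.

    Twins occupy the regions immediately after the seed within its
    hemisphere. Seed-twin and twin-twin edges are set to a strong intra-type
    weight (90th percentile of the seed's non-zero edges) so the twins are
    tightly mutually coupled, as homotopic/structural twins are.
    """
    k = spec.planted_twin_size
    if k == 0:
        return w
    s = spec.twin_seed_region
    h = spec.n_per_hemisphere
    offset = h if s >= h else 0
    s_local = s - offset
    twin_idx = [(s_local + 1 + t) % h + offset for t in range(k)]
    seed_row = w[s].copy()
    strong = np.quantile(seed_row[seed_row > 0], 0.9) if np.any(seed_row > 0) else 1.0
    for t in twin_idx:
        row = seed_row * (1.0 + 0.01 * rng.standard_normal(w.shape[0]))
        row = np.clip(row, 0.0, None)
        w[t, :] = row
        w[:, t] = row
        w[t, t] = 0.0
    group = [s] + list(twin_idx)
    for a in group:
        for b in group:
            if a != b:
                w[a, b] = strong
    return w


def generate_connectome(spec: CohortSpec, subject_index: int) -> Connectome:
    """One subject's connectome: group skeleton x subject jitter, normalised
    to unit maximum nodal strength.

    Deterministic given ``(spec.seed, subject_index)`` and independent of
    which other subjects are generated.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    skeleton_rng = np.random.default_rng([spec.seed, 0])
    w = _group_skeleton(spec, skeleton_rng)
    w = _plant_twins(spec, w, skeleton_rng)

    if spec.subject_jitter > 0:
        rng = np.random.default_rng([spec.seed, 1, subject_index])
        n = spec.n_regions
        iu, ju = np.triu_indices(n, k=1)
        noise = np.exp(spec.subject_jitter * rng.standard_normal(iu.size))
        jit = np.ones((n, n))
        jit[iu, ju] = noise
        jit[ju, iu] = noise
        w = w * jit

    # Normalise to unit maximum nodal strength: the stability threshold of
    # the coupled mean-field model scales with G times the largest row sum,
    # so this pins the critical G at the same value for every subject and
    # cohort (instead of being hostage to the single heaviest log-normal
    # tail edge, as matrix-max scaling would be).
    m = w.sum(axis=1).max()
    if m > 0:
        w = w / m
    return Connectome(w, spec.region_labels(), ["L"] * spec.n_per_hemisphere + ["R"] * spec.n_per_hemisphere)


def generate_cohort(spec: CohortSpec) -> list[Connectome]:
    """All subjects of the cohort (shared skeleton, per-subject jitter)."""
    return [generate_connectome(spec, i) for i in range(spec.n_subjects)]


def write_cohort(spec: CohortSpec, out_dir) -> list[Path]:
    """Write each subject's SC as TSV plus a JSON sidecar of cohort parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, c in enumerate(generate_cohort(spec)):
        p = out / f"sub-{i:03d}_sc.tsv"
        write_connectome(c, p)
        paths.append(p)
    with open(out / "cohort_spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
    return paths
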
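"""Dynamically similar areas, SSA/DSA overlap, correlations and group PA.

Dynamically similar areas (DSAs) of a lesion site are the regions that both
took longest to regain the homeostatic balance after the lesion (top
fraction by re-adjustment time RT) and changed their local inhibitory
weights most (top fraction by |dJJ|): the intersection of the two top-N
rank sets, N = round(fraction x n_regions). Overlap with the structurally
similar areas (SSAs, from the healthy connectome's Jaccard profile) is
quantified as |SSA ∩ DSA| / |DSA|.

The group-level probability of appearance (PA) of a region is the fraction
of subjects in whose SSA (or DSA) set it appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectome import AreaSet, top_n_count, _ranked_top

__all__ = [
    "DSASelection",
    "OverlapReport",
    "GroupPA",
    "CorrelationResult",
    "select_dsa",
    "overlap",
    "measure_correlations",
    "common_top_areas",
    "probability_of_appearance",
]


@dataclass
class DSASelection:
    dsa: AreaSet
    top_rt: AreaSet
    top_djj: AreaSet
    fraction: float


@dataclass
class OverlapReport:
    common: frozenset[int]
    overlap_fraction: float
    denominator_convention: str = "|DSA|"
    empty_dsa: bool = False


@dataclass
class GroupPA:
    pa: np.ndarray
    n_subjects: int
    measure: str


@dataclass
class CorrelationResult:
    """Pearson r and OLS line for one pair of regional measures."""

    pair: tuple[str, str]
    r: float
    p_value: float
    slope: float
    intercept: float
    degenerate: bool = False


def _masked_top(values: np.ndarray, lesion: int | None, n_top: int,
                source: str, fraction: float,
                exclude_zero: bool = False) -> AreaSet:
    vals = np.asarray(values, dtype=float)
    work = np.where(np.isnan(vals), -np.inf, vals)
    ranked = _ranked_top(work, lesion, n_top)
    if exclude_zero:
        # a region whose measure is exactly 0 never responded to the lesion;
        # membership by tie-breaking alone would be meaningless
        ranked = tuple(i for i in ranked if work[i] > 0.0)
    return AreaSet(members=frozenset(ranked), fraction=fraction, source=source,
                   ranked=ranked)


def select_dsa(rt: np.ndarray, djj: np.ndarray, lesion: int | None = None,
               fraction: float = 0.25) -> DSASelection:
    """DSA = (top-N by RT) ∩ (top-N by |dJJ|), N = round(fraction x n_regions).

    The lesioned node is excluded from candidacy (NaN entries are treated as
    masked as well); ties break by ascending region index. Regions whose RT
    or |dJJ| is exactly zero — regions the lesion never pushed out of the
    homeostatic band — are not eligible, so the rank sets (and hence the
    DSA) may hold fewer than N members.
    """
    rt = np.asarray(rt, dtype=float)
    djj = np.asarray(djj, dtype=float)
    if rt.shape != djj.shape:
        raise ValueError("rt and djj must have equal length")
    n = len(rt)
    n_top = min(top_n_count(fraction, n), n - (1 if lesion is not None else 0))
    if np.nansum(np.where(np.arange(n) == lesion, 0.0, rt)) == 0.0:
        warnings.warn("all re-adjustment times are zero; DSA selection is "
                      "driven by tie-breaking only", RuntimeWarning, stacklevel=2)
    top_rt = _masked_top(rt, lesion, n_top, "DSA_rt", fraction, exclude_zero=True)
    top_djj = _masked_top(np.abs(djj), lesion, n_top, "DSA_djj", fraction,
                          exclude_zero=True)
    members = top_rt.members & top_djj.members
    dsa = AreaSet(members=members, fraction=fraction, source="DSA",
                  ranked=tuple(sorted(members)))
    return DSASelection(dsa=dsa, top_rt=top_rt, top_djj=top_djj, fraction=fraction)


def overlap(ssa: AreaSet, dsa_sel: DSASelection | AreaSet) -> OverlapReport:
    """Overlap of SSA and DSA member sets, fraction |SSA ∩ DSA| / |DSA|."""
    dsa = dsa_sel.dsa if isinstance(dsa_sel, DSASelection) else dsa_sel
    common = frozenset(ssa.members & dsa.members)
    if len(dsa.members) == 0:
        warnings.warn("empty DSA; overlap fraction reported as 0",
                      RuntimeWarning, stacklevel=2)
        return OverlapReport(common=common, overlap_fraction=0.0, empty_dsa=True)
    return OverlapReport(common=common,
                         overlap_fraction=len(common) / len(dsa.members))


def _pairwise(x: np.ndarray, y: np.ndarray, pair: tuple[str, str]) -> CorrelationResult:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"constant vector in correlation {pair}; r reported as 0",
                      RuntimeWarning, stacklevel=3)
        return CorrelationResult(pair=pair, r=0.0, p_value=1.0, slope=0.0,
                                 intercept=float(np.mean(y)) if len(y) else 0.0,
                                 degenerate=True)
    lr = stats.linregress(x, y)
    return CorrelationResult(pair=pair, r=float(lr.rvalue), p_value=float(lr.pvalue),
                             slope=float(lr.slope), intercept=float(lr.intercept))


def measure_correlations(jc: np.ndarray, rt: np.ndarray, djj: np.ndarray,
                         lesion: int | None = None) -> dict[str, CorrelationResult]:
    """Pearson r and OLS fits for (JC, RT), (JC, |dJJ|) and (RT, |dJJ|).

    The lesioned node is masked out of all three vectors.
    """
    jc = np.asarray(jc, dtype=float).copy()
    rt = np.asarray(rt, dtype=float).copy()
    adjj = np.abs(np.asarray(djj, dtype=float))
    if lesion is not None:
        jc[lesion] = np.nan
        rt[lesion] = np.nan
        adjj[lesion] = np.nan
    return {
        "jc_rt": _pairwise(jc, rt, ("JC", "RT")),
        "jc_djj": _pairwise(jc, adjj, ("JC", "|dJJ|")),
        "rt_djj": _pairwise(rt, adjj, ("RT", "|dJJ|")),
    }


def common_top_areas(x: np.ndarray, y: np.ndarray, fraction: float = 0.25,
                     lesion: int | None = None) -> AreaSet:
    """Regions in the top fraction of both measures (intersection of rank sets)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    n_top = min(top_n_count(fraction, n), n - (1 if lesion is not None else 0))
    top_x = _masked_top(x, lesion, n_top, "top_x", fraction)
    top_y = _masked_top(y, lesion, n_top, "top_y", fraction)
    members = top_x.members & top_y.members
    return AreaSet(members=members, fraction=fraction, source="overlap",
                   ranked=tuple(sorted(members)))


def probability_of_appearance(sets_per_subject: list[AreaSet], n_regions: int,
                              measure: str = "SSA") -> GroupPA:
    """Per-region appearance count across subjects / number of subjects."""
    if not sets_per_subject:
        raise ValueError("need at least one subject")
    counts = np.zeros(n_regions)
    for s in sets_per_subject:
        for i in s.members:
            counts[i] += 1
    return GroupPA(pa=counts / len(sets_per_subject),
                   n_subjects=len(sets_per_subject), measure=measure)
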
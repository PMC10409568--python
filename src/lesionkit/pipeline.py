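"""Three-condition virtual-lesion workflow per subject, and group pooling.

Per subject and lesion site the workflow runs:

1. healthy — intact connectome: Jaccard profile of the prospective lesion
   site (SSA), inhibitory weights J tuned by FIC, simulated healthy FC;
2. altered — lesioned connectome with J frozen at the healthy values (the
   acute state: excitation lost, inhibition not yet re-adjusted), simulated
   altered FC;
3. reorganized — lesioned connectome re-tuned by FIC starting from the
   healthy J (yielding J', the re-adjustment times RT and dJJ = J' - J),
   simulated re-organized FC.

SSA/DSA selection, their overlap and the JC-RT/JC-|dJJ|/RT-|dJJ|
correlations are then computed, and everything is optionally written to an
output directory with a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import (Connectome, apply_lesion, jaccard_profile,
                         nodal_strength, read_connectome, select_ssa,
                         write_connectome, AreaSet)
from .dmf import DMFParams, simulate
from .fic import FICResult, run_fic, weight_change
from .hemodynamics import FCMatrix, bold_from_activity, fc_from_bold
from .similarity import (DSASelection, OverlapReport, measure_correlations,
                         overlap, probability_of_appearance, select_dsa)
from .fc_stats import paired_edge_ttest
from .synthetic import CohortSpec, generate_connectome

__all__ = ["RunConfig", "LesionResult", "SubjectResult", "GroupResult",
           "run_subject", "run_group", "ci_profile", "hub_lesion_sites"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full run (synthetic cohort or SC directory)."""

    cohort: CohortSpec | None = None
    sc_dir: str | None = None
    lesion_sites: list = field(default_factory=list)   # labels or indices
    fraction: float = 0.25
    dmf: DMFParams = field(default_factory=DMFParams)
    fic: dict = field(default_factory=dict)            # run_fic kwargs
    duration: float = 600.0      # s of simulated activity per condition
    transient: float = 120.0     # s discarded
    TR: float = 2.0              # s, BOLD sampling
    record_stride: int = 10      # integration steps between recorded samples
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "cohort" in kw and kw["cohort"] is not None:
            kw["cohort"] = CohortSpec(**kw["cohort"])
        if "dmf" in kw and kw["dmf"] is not None:
            kw["dmf"] = DMFParams(**kw["dmf"])
        return cls(**kw)

    def n_subjects(self) -> int:
        if self.cohort is not None:
            return self.cohort.n_subjects
        return len(sorted(Path(self.sc_dir).glob("*_sc.tsv")))

    def load_subject(self, subject: int) -> Connectome:
        if self.cohort is not None:
            return generate_connectome(self.cohort, subject)
        paths = sorted(Path(self.sc_dir).glob("*_sc.tsv"))
        return read_connectome(paths[subject])


def ci_profile() -> dict:
    """Reduced-duration settings for quick runs: 80 s simulations with a
    20 s transient and a 60-window FIC budget."""
    return {"duration": 80.0, "transient": 20.0,
            "fic": {"max_windows": 60}, "record_stride": 10}


def hub_lesion_sites(c: Connectome, n_sites: int = 2, hemisphere: str = "L") -> list[int]:
    """Indices of the ``n_sites`` strongest regions of one hemisphere."""
    strength = nodal_strength(c)
    idx = c.hemisphere_indices(hemisphere)
    order = idx[np.argsort(-strength[idx], kind="stable")]
    return [int(i) for i in order[:n_sites]]


@dataclass
class LesionResult:
    lesion: int
    jc: np.ndarray
    ssa: AreaSet
    rt: np.ndarray
    djj: np.ndarray
    dsa: DSASelection
    overlap: OverlapReport
    correlations: dict
    fic_lesioned: FICResult
    fc_altered: FCMatrix
    fc_reorganized: FCMatrix


@dataclass
class SubjectResult:
    subject: int
    connectome: Connectome
    fic_healthy: FICResult
    fc_healthy: FCMatrix
    lesions: dict[int, LesionResult]


@dataclass
class GroupResult:
    subjects: list[SubjectResult]
    pa_ssa: dict
    pa_dsa: dict
    contrasts: dict


def _resolve_site(c: Connectome, site) -> int:
    return site if isinstance(site, (int, np.integer)) else c.index_of(site)


def _condition_fc(c: Connectome, p: DMFParams, J: np.ndarray, cfg: RunConfig,
                  seed: int, condition: str) -> FCMatrix:
    sim = simulate(c, p, J=J, duration=cfg.duration, transient=cfg.transient,
                   record_stride=cfg.record_stride, seed=seed)
    act = sim.S_E_trace.T
    act = act - act.mean(axis=1, keepdims=True)
    bold = bold_from_activity(act, dt=sim.trace_dt, TR=cfg.TR,
                              transient=cfg.transient)
    return fc_from_bold(bold, condition=condition)


def _stage_seed(cfg: RunConfig, subject: int, stage: int) -> int:
    ss = np.random.SeedSequence([cfg.seed, subject, stage])
    return int(ss.generate_state(1)[0] % (2**31))


def run_subject(cfg: RunConfig, subject: int, compute_fc: bool = True) -> SubjectResult:
    """Execute the three-condition workflow for one subject.

    ``compute_fc=False`` skips the BOLD/FC stages (structural and
    homeostatic measures only), which is enough for SSA/DSA analyses.
    """
    t0 = time.time()
    c = cfg.load_subject(subject)
    p = cfg.dmf
    fic_h = run_fic(c, p, seed=_stage_seed(cfg, subject, 0), **cfg.fic)
    fc_h = (_condition_fc(c, p, fic_h.J_final, cfg,
                          _stage_seed(cfg, subject, 1), "healthy")
            if compute_fc else FCMatrix(np.eye(c.n_regions), "healthy"))

    lesions: dict[int, LesionResult] = {}
    for site in cfg.lesion_sites:
        node = _resolve_site(c, site)
        prof = jaccard_profile(c, node)
        ssa = select_ssa(prof, cfg.fraction)
        c_les = apply_lesion(c, node)

        fc_alt = (_condition_fc(c_les, p, fic_h.J_final, cfg,
                                _stage_seed(cfg, subject, 10 + node), "altered")
                  if compute_fc else FCMatrix(np.eye(c.n_regions), "altered"))

        fic_l = run_fic(c_les, p, J_init=fic_h.J_final,
                        seed=_stage_seed(cfg, subject, 20 + node), **cfg.fic)
        fc_re = (_condition_fc(c_les, p, fic_l.J_final, cfg,
                               _stage_seed(cfg, subject, 30 + node), "reorganized")
                 if compute_fc else FCMatrix(np.eye(c.n_regions), "reorganized"))

        wc = weight_change(fic_h.J_final, fic_l.J_final, lesion=node)
        dsa = select_dsa(fic_l.RT, wc.dJJ, lesion=node, fraction=cfg.fraction)
        ov = overlap(ssa, dsa)
        corr = measure_correlations(prof.jc, fic_l.RT, wc.dJJ, lesion=node)
        lesions[node] = LesionResult(
            lesion=node, jc=prof.jc, ssa=ssa, rt=fic_l.RT, djj=wc.dJJ,
            dsa=dsa, overlap=ov, correlations=corr, fic_lesioned=fic_l,
            fc_altered=fc_alt, fc_reorganized=fc_re)
    logger.info("subject %d done in %.1f s", subject, time.time() - t0)
    return SubjectResult(subject=subject, connectome=c, fic_healthy=fic_h,
                         fc_healthy=fc_h, lesions=lesions)


def run_group(cfg: RunConfig, subjects: list[int] | None = None,
              compute_fc: bool = True) -> GroupResult:
    """Run all subjects; pool PA tables and paired FC contrasts per lesion."""
    if subjects is None:
        subjects = list(range(cfg.n_subjects()))
    if not subjects:
        raise ValueError("no subjects to run")
    results = [run_subject(cfg, s, compute_fc=compute_fc) for s in subjects]

    n = results[0].connectome.n_regions
    sites = sorted({node for r in results for node in r.lesions})
    pa_ssa, pa_dsa, contrasts = {}, {}, {}
    for node in sites:
        have = [r for r in results if node in r.lesions]
        pa_ssa[node] = probability_of_appearance(
            [r.lesions[node].ssa for r in have], n, measure="SSA")
        pa_dsa[node] = probability_of_appearance(
            [r.lesions[node].dsa.dsa for r in have], n, measure="DSA")
        if compute_fc and len(have) >= 3:
            contrasts[node] = {
                "healthy_vs_altered": paired_edge_ttest(
                    [r.fc_healthy for r in have],
                    [r.lesions[node].fc_altered for r in have],
                    alpha=cfg.alpha, contrast="healthy_vs_altered"),
                "altered_vs_reorganized": paired_edge_ttest(
                    [r.lesions[node].fc_altered for r in have],
                    [r.lesions[node].fc_reorganized for r in have],
                    alpha=cfg.alpha, contrast="altered_vs_reorganized"),
            }
    return GroupResult(subjects=results, pa_ssa=pa_ssa, pa_dsa=pa_dsa,
                       contrasts=contrasts)


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def write_subject_result(res: SubjectResult, cfg: RunConfig, out_dir) -> dict:
    """Persist one subject's artifacts; returns the manifest entry."""
    out = Path(out_dir) / f"sub-{res.subject:03d}"
    out.mkdir(parents=True, exist_ok=True)
    c = res.connectome
    labels = c.region_labels
    entry = {"subject": res.subject, "files": {}, "seeds": {"base": cfg.seed},
             "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def _fc(path, fc):
        pd.DataFrame(fc.values, index=labels, columns=labels).to_csv(path, sep="\t")

    hp = out / "fic_healthy.csv"
    pd.DataFrame({"region": labels, "J": res.fic_healthy.J_final,
                  "RT": res.fic_healthy.RT, "firing": res.fic_healthy.firing,
                  "converged": res.fic_healthy.converged}).to_csv(hp, index=False)
    entry["files"]["fic_healthy"] = hp.name
    fch = out / "fc_healthy.tsv"
    _fc(fch, res.fc_healthy)
    entry["files"]["fc_healthy"] = fch.name

    for node, lr in res.lesions.items():
        tag = labels[node]
        rep = out / f"lesion-{tag}_report.csv"
        pd.DataFrame({
            "region": labels, "jc": lr.jc, "rt": lr.rt, "djj": lr.djj,
            "in_ssa": [i in lr.ssa.members for i in range(c.n_regions)],
            "in_dsa": [i in lr.dsa.dsa.members for i in range(c.n_regions)],
            "in_overlap": [i in lr.overlap.common for i in range(c.n_regions)],
        }).to_csv(rep, index=False)
        entry["files"][f"lesion-{tag}_report"] = rep.name
        for cond, fc in (("altered", lr.fc_altered), ("reorganized", lr.fc_reorganized)):
            path = out / f"lesion-{tag}_fc_{cond}.tsv"
            _fc(path, fc)
            entry["files"][f"lesion-{tag}_fc_{cond}"] = path.name
        stats = {
            "overlap_fraction": lr.overlap.overlap_fraction,
            "denominator_convention": lr.overlap.denominator_convention,
            "correlations": {k: {"r": v.r, "slope": v.slope,
                                 "intercept": v.intercept, "p": v.p_value}
                             for k, v in lr.correlations.items()},
        }
        sp = out / f"lesion-{tag}_similarity.json"
        with open(sp, "w") as fh:
            json.dump(stats, fh, indent=2)
        entry["files"][f"lesion-{tag}_similarity"] = sp.name

    with open(out / "manifest.json", "w") as fh:
        json.dump(entry, fh, indent=2)
    return entry


def run_to_disk(cfg: RunConfig, subjects: list[int] | None = None,
                force: bool = False, compute_fc: bool = True) -> list[dict]:
    """Run subjects and persist artifacts under ``cfg.out_dir``.

    Completed subjects (existing manifest) are skipped unless ``force``.
    """
    if cfg.out_dir is None:
        raise ValueError("cfg.out_dir is not set")
    if subjects is None:
        subjects = list(range(cfg.n_subjects()))
    entries = []
    for s in subjects:
        man = Path(cfg.out_dir) / f"sub-{s:03d}" / "manifest.json"
        if man.exists() and not force:
            logger.info("subject %d already complete; skipping", s)
            with open(man) as fh:
                entries.append(json.load(fh))
            continue
        res = run_subject(cfg, s, compute_fc=compute_fc)
        entries.append(write_subject_result(res, cfg, cfg.out_dir))
    return entries
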
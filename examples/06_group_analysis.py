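"""Group-level probability of appearance (PA) of SSAs and DSAs.

Runs the structural + homeostatic stages for every subject of a small
cohort with the same lesion site and reports, per region, the fraction of
subjects in which it is selected — PA = 1 means the region is predicted as
compensatory in every subject despite inter-subject anatomical variability.
"""

import lesionkit as lk

spec = lk.CohortSpec(n_subjects=5, seed=11)
prof = lk.ci_profile()
c0 = lk.generate_connectome(spec, 0)
hub = lk.hub_lesion_sites(c0, 1)[0]
cfg = lk.RunConfig(cohort=spec, lesion_sites=[hub], dmf=lk.DMFParams(seed=0),
                   duration=prof["duration"], transient=prof["transient"],
                   fic=prof["fic"], seed=3)

grp = lk.run_group(cfg, compute_fc=False)
labels = c0.region_labels
print(f"lesion at {labels[hub]}; {spec.n_subjects} subjects\n")
for measure, pa in (("SSA", grp.pa_ssa[hub]), ("DSA", grp.pa_dsa[hub])):
    top = sorted(enumerate(pa.pa), key=lambda kv: -kv[1])[:8]
    print(f"{measure} probability of appearance (top regions):")
    for idx, val in top:
        if val > 0:
            print(f"  {labels[idx]}: {val:.2f}")
    print()
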
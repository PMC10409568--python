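"""Structurally similar areas (SSAs) of a prospective lesion site.

Computes the weighted Jaccard profile of the strongest left-hemisphere
region on a healthy synthetic connectome and selects the top 25% of regions
as SSAs — the structurally defined candidates for post-lesion compensation.
"""

import lesionkit as lk

c = lk.generate_connectome(lk.CohortSpec(n_subjects=1, seed=42), 0)
site = lk.hub_lesion_sites(c, 1)[0]
print(f"prospective lesion site: {c.region_labels[site]} "
      f"(strength {lk.nodal_strength(c)[site]:.2f})")

profile = lk.jaccard_profile(c, site)
ssa = lk.select_ssa(profile, fraction=0.25)

print(f"\ntop 25% = {len(ssa.members)} SSAs (JC in brackets):")
for rank, idx in enumerate(ssa.ranked, start=1):
    tag = " <- contralesional homologue" if idx == (site + 34) % 68 else ""
    print(f"  {rank:2d}. {c.region_labels[idx]}  [{profile.jc[idx]:.3f}]{tag}")
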
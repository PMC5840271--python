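"""Full cohort analysis: planted-effect recovery through the whole pipeline.

Simulates the default two-group study (8 subjects, hours 3/24/48/72; group
1 with declining uptake, group 2 with rising uptake and extra growth of
its vascularized-shell hot spots), runs preprocessing, merge trees,
diagrams, measures, and the time-series statistics, and prints which
evaluation properties each method satisfies:

(i)   separates the groups' uptake trends directly,
(ii)  separates high- from low-region trends within a group,
(iii) (ii) holds in exactly one group — differential heterogeneity.
"""

import topouptake as tu

cohort = tu.generate_cohort(tu.PhantomParams(seed=1))
truth = cohort.truth
print(f"planted: group slope difference sign {truth.group_slope_diff_sign}, "
      f"heterogeneity only in group 2 = {truth.expect_property_iii}")

bundle = tu.run_pipeline(cohort, tu.RunConfig())
print(f"{len(bundle.trees)} merge trees, {len(bundle.points)} diagram points\n")

print(f"{'method':<22} {'i':>5} {'ii(G1)':>7} {'ii(G2)':>7} {'iii':>5}")
for rep in bundle.properties:
    print(f"{rep.method:<22} {str(rep.property_i):>5} "
          f"{str(rep.property_ii_group1):>7} {str(rep.property_ii_group2):>7} "
          f"{str(rep.property_iii):>5}")

rep = bundle.property_report("childhood:h24:y")
print("\nH24-normalized childhood y-coordinates: between-group p = "
      f"{rep.p_values['between_all']:.2e}, within-group p (G1, G2) = "
      f"({rep.p_values['within_group1']:.3f}, {rep.p_values['within_group2']:.4f})")
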
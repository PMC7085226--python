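"""Pre- vs post-therapy comparison from group summary statistics.

Given only each group's n, mean and SD, the pooled two-sample t-test
reproduces the significance calls of a published two-group table. The same
code path also compares per-sample tables from a simulated cohort.
"""

from mpmquant import CohortSpec, GroupSummary, compare_groups, draw_cohort_targets, t_test_from_summary

# published-style group summaries: nuclear area (px^2) and collagen (%)
pre_area = GroupSummary("pre", "nuclear_area_px2", 30, 596.56, 208.69)
post_area = GroupSummary("post", "nuclear_area_px2", 30, 856.22, 255.74)
pre_coll = GroupSummary("pre", "collagen_content_pct", 30, 22.81, 10.23)
post_coll = GroupSummary("post", "collagen_content_pct", 30, 36.10, 12.42)

for name, a, b in (("nuclear area", pre_area, post_area),
                   ("collagen    ", pre_coll, post_coll)):
    res = t_test_from_summary(a, b, variant="pooled")
    print(f"{name}: t = {res.t_statistic:.4f}, df = {res.degrees_of_freedom:.0f}, "
          f"p = {res.p_value:.2e} ({'significant' if res.significant else 'ns'})")

# same comparison on per-sample metric targets drawn for a synthetic cohort
targets = draw_cohort_targets(CohortSpec(master_seed=0)).rename(
    columns={"target_nuclear_area_px2": "nuclear_area_px2",
             "target_collagen_pct": "collagen_content_pct"}
)
table = compare_groups(targets[targets.group == "pre"], targets[targets.group == "post"])
print()
print(table[["metric", "mean_pre", "sd_pre", "mean_post", "sd_post",
             "t_statistic", "p_bin"]].to_string(index=False))
# Both metrics separate at p < 0.001 from the summaries; the simulated
# cohort reproduces that at its drawn effect sizes.
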
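"""Relate the ApEn morphology score to disability and progression.

On a synthetic cohort with known ground truth: link each visit to the
nearest EDSS record within a year, summarise foot-trace ApEn per EDSS
level, and compute the 2-year progression AUC of baseline foot vs hand
ApEn.  The foot association should be the stronger one, because from
EDSS 4 upward the scale is dominated by walking ability.
"""

from mepmorph import (
    ApEnParams,
    apen,
    edss_distribution_summary,
    generate_cohort,
    link_edss,
    progression_auc,
    progression_label,
    select_t1,
)

cohort = generate_cohort(150, rng_seed=9)
params = ApEnParams()

scores = {
    row["trace_id"]: apen(cohort.trace_by_id(row["trace_id"]).samples, params).normalized
    for _, row in cohort.truth.iterrows()
    if row["artifact"] == ""
}

visit_edss = link_edss(cohort.visits, cohort.edss)
foot = cohort.truth[(cohort.truth["limb"] == "AH") & (cohort.truth["artifact"] == "")]
vals = [scores[t] for t in foot["trace_id"]]
levels = [visit_edss[v] for v in foot["visit_id"]]

print("foot-trace normalised ApEn by EDSS level:")
summary = edss_distribution_summary(vals, levels)
for _, row in summary.iterrows():
    print(f"  EDSS {row['edss']:>4.1f}  n={row['n']:3d}  mean ApEn={row['mean']:.3f}")

# 2-year progression from the EDSS records themselves
rows = []
for pid, grp in cohort.edss.groupby("patient_id"):
    t0_date = grp["date"].min()
    baseline = grp.loc[grp["date"] == t0_date, "edss"].iloc[0]
    t1 = select_t1(grp, t0_date)
    if t1 is None:
        continue
    limb_apen = {}
    for limb in ("AH", "APB"):
        ids = cohort.truth[
            (cohort.truth["patient_id"] == pid)
            & (cohort.truth["limb"] == limb)
            & (cohort.truth["artifact"] == "")
        ]["trace_id"]
        limb_apen[limb] = float(sum(scores[t] for t in ids) / max(len(ids), 1))
    rows.append((progression_label(baseline, t1[0]), limb_apen["AH"], limb_apen["APB"]))

progressed = [r[0] for r in rows]
print(f"\n{sum(progressed)}/{len(rows)} patients progressed within ~2 years")
print(f"progression AUC, foot ApEn: {progression_auc([r[1] for r in rows], progressed):.3f}")
print(f"progression AUC, hand ApEn: {progression_auc([r[2] for r in rows], progressed):.3f}")
print("Foot morphology predicts walking-driven disability progression")
print("better than hand morphology, as expected from the EDSS design.")
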
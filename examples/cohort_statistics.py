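"""Group-level statistics on a simulated gestational-age cohort.

Draws per-subject interval means for three gestational-age groups
(16/21/29 subjects, interval targets near the published group means),
renders the group report — mean ± SE, Kruskal-Wallis, pairwise
Mann-Whitney and Spearman age correlations — and prints it.
"""
import numpy as np

from swdus import GroupSpec, SubjectSummary, full_group_stats, generate_cohort

specs = [
    GroupSpec("early", 16, {"ict": 44.9, "vet": 138.7, "irt": 77.5},
              {"ict": 6.0, "vet": 8.0, "irt": 6.0}, week_range=(16, 29)),
    GroupSpec("mid", 21, {"ict": 35.8, "vet": 144.5, "irt": 74.8},
              {"ict": 5.0, "vet": 8.0, "irt": 6.0}, week_range=(30, 35)),
    GroupSpec("late", 29, {"ict": 38.0, "vet": 134.4, "irt": 78.8},
              {"ict": 5.0, "vet": 8.0, "irt": 7.0}, week_range=(36, 41)),
]
subjects = generate_cohort(specs, seed=7, render_signals=False)

summaries = []
for s in subjects:
    # per-subject truth: reconstruct interval means from the drawn offsets
    off = s.config.event_offsets_ms
    ict = off["ao"] - off["mc"]
    vet = off["ac"] - off["ao"]
    irt = off["mo"] - off["ac"]
    pep = 25.0 + ict
    summaries.append(
        SubjectSummary(
            s.subject_id, s.group_label,
            {"ict": ict, "vet": vet, "irt": irt, "pep": pep, "sti": pep + vet},
            n_beats=140, week=s.week,
        )
    )

table = full_group_stats(summaries, ["early", "mid", "late"])
print("mean +- SE per group (ms):")
for name in ("ict", "vet", "irt", "pep", "sti"):
    sub = table.summary[table.summary.interval == name]
    cells = "  ".join(f"{r.group}: {r['mean']:6.1f} +- {r.se:4.1f}" for _, r in sub.iterrows())
    print(f"  {name.upper():>4} {cells}")
print("\nKruskal-Wallis across the three groups:")
for _, r in table.kruskal.iterrows():
    print(f"  {r.interval.upper():>4}: H = {r.H:5.2f}, p = {r.p:.4f}")
print("\npairwise Mann-Whitney p-values (raw):")
for _, r in table.pairwise.iterrows():
    print(f"  {r.interval.upper():>4} {r['pair']:>16}: p = {r.p:.4f}")
print("\nintervals with well-separated group means (ICT, VET, PEP) come out")
print("strongly significant; the closer ones (IRT, STI) sit near p = 0.05 —")
print("the report mirrors a real cohort analysis end to end.")
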
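"""Feature-band-combination screening by summed standard deviations.

Scores the standard candidate combinations for each class-specific index on
synthetic samples (smallest SD sum wins = most stable combination), then
replays the selection rule on the published candidate scores, where it picks
the same winners the published screening reports.
"""

from vegindex import (default_profiles, select_combination, select_from_scores,
                      simulate_sample_table, standard_candidates)
from vegindex.reference import SCREENING_CANDIDATES

samples = simulate_sample_table(default_profiles(), n_per_class=50, seed=1)

print("screening on synthetic samples (x10^4 reflectance scale):")
for target, cands in standard_candidates().items():
    report = select_combination(cands, samples)
    print(f"\n  target class: {target}")
    for _, row in report.to_frame().iterrows():
        mark = " <- selected" if row["selected"] else ""
        print(f"    {row['combination']:24s} {row['sd_sum']:8.2f}{mark}")

print("\nselection replayed on the published candidate scores:")
for target, cands in standard_candidates().items():
    scores = [s for _, s in SCREENING_CANDIDATES[target]]
    report = select_from_scores(cands, scores)
    print(f"  {target:12s} -> {report.selected.label} "
          f"({report.selected_score:.2f})")
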
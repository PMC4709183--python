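"""Build a speller session schedule and verify its counting identities.

The 5x6 character grid flashes one row or column at a time in randomized
blocks of 11; the attended character's row and column are the two target
stimuli per block.
"""

from plvspeller import build_schedule, default_matrix, expected_counts

matrix = default_matrix()
plan = build_schedule(matrix, characters=list(range(14)), n_repetitions=15,
                      rng_seed=0)

n_target, n_nontarget = expected_counts(plan)
print(f"matrix: {matrix.n_rows} rows x {matrix.n_cols} cols "
      f"-> {matrix.n_stimuli} stimuli per block")
print(f"total flashes: {plan.n_flashes}")
print(f"closed-form counts: {n_target} target, {n_nontarget} non-target")
print(f"enumerated counts:  {int(plan.schedule.is_target.sum())} target, "
      f"{int((~plan.schedule.is_target).sum())} non-target")
# 14 characters x 15 repetitions give 420 target flashes (2 per block) and
# 1890 non-target flashes (9 per block); enumeration matches the formula.
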
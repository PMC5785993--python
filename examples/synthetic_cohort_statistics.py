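"""Grade a synthetic 5-vs-4 mouse cohort and test it day by day.

Generates ordinal tumour-grade trajectories (logistic latent growth, 2-day
treatment delay), runs the exact Mann-Whitney comparison on every follow-up
day and estimates the growth delay.  Also reproduces the reference p-values
from the shipped synthetic grade table, whose day-6 grades are completely
separated (the exact one-sided minimum p = 1/126) and whose day-7 grades
give p = 4/126.
"""

from importlib.resources import files

from enafl import (GradeTrajectoryParams, daily_group_comparison,
                   gen_grade_trajectories, growth_delay_estimate)
from enafl.io import read_grades_csv

series, truth = gen_grade_trajectories(GradeTrajectoryParams(seed=0))
print("simulated cohort (4 control vs 5 irradiated, 7 days):")
print(daily_group_comparison(series).to_string(index=False))
delay = growth_delay_estimate(series)
print(f"estimated growth delay: {delay.delay_days:+.1f} days "
      f"(generator truth: {truth['delay_days']:+.1f} days; single cohorts")
print("are noisy -- the median estimate over 200 cohorts recovers 2 days)\n")

fixture = files("enafl") / "data" / "grades_synthetic.csv"
ref = read_grades_csv(str(fixture))
table = daily_group_comparison(ref)
print("shipped synthetic grade table:")
print(table[table.day >= 5].to_string(index=False))
print("day 6 shows the exact one-sided minimum p = 1/126 = 0.0079 forced by")
print("complete separation of five treated below four control grades;")
print("day 7 relaxes to p = 4/126 = 0.0317.")
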
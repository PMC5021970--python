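"""Two-group statistics on a synthetic per-ganglion feature cohort.

Simulates 65 patient and 41 control ganglia with the documented effect
directions (patients: smaller ganglia, more mitochondria per volume, higher
mitochondrial mass), then runs the label-permutation test on each feature and
a Spearman correlation against the motor score.
"""

from mitoganglia.io import MITO_FEATURES
from mitoganglia.simulate import CohortSimSpec, simulate_cohort
from mitoganglia.stats import group_feature_tests, spearman

table = simulate_cohort(CohortSimSpec(seed=1))
print(f"cohort: {len(table)} ganglia "
      f"({(table.group == 'patient').sum()} patient / {(table.group == 'control').sum()} control)")

tests = group_feature_tests(table, ["GanglionVolume"] + MITO_FEATURES,
                            n_perm=10_000, seed=17)
print(tests[["feature", "mean_patient", "mean_control", "p_value"]].to_string(index=False))
# Small p-values on GanglionVolume (smaller in patients), MitoCount and
# MitoVolumeTotal (both higher in patients) recover the simulated effects.

patients = table[table.group == "patient"]
rho, p = spearman(patients.MitoVolumeMean, patients.UPDRSIII)
print(f"\nSpearman MitoVolumeMean vs UPDRS-III (patients): rho = {rho:.3f}, p = {p:.3f}")
# Negative rho: mean mitochondrial volume declines as motor impairment rises.
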
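"""Discover a metabolomic signature on a simulated 20 v 20 cohort.

Generates a cohort with planted pathway shifts (increased ceramides and
phosphatidylcholines, decreased purines, ...), Z-scores every sample
against the control reference, fits a 2-component PLS-DA and applies the
joint selection rule: VIP > 1.5 AND Mann-Whitney p <= 0.05.
"""

import metsig as ms

config = ms.CohortConfig(seed=42)
cohort, truth = ms.generate_cohort(config)
z = ms.zscore_against_controls(ms.log_transform(cohort))

model = ms.fit_plsda(z, n_components=2)
screen = ms.screen_metabolites(z, model)

print(f"cohort: {cohort.n_cases} cases vs {cohort.n_controls} controls, "
      f"{len(cohort.metabolite_ids)} metabolites")
print(f"significant metabolites (VIP > 1.5 and U p <= 0.05): {screen.n_significant}")
print("\ntop 10 by VIP:")
print(screen.table.head(10)[["vip", "u_p", "direction", "significant"]].round(4))

planted = truth["planted_z_shifts"]
recovered = [m for m in screen.table[screen.table.significant].index if m in planted]
print(f"\n{len(recovered)} of the significant metabolites carry a planted shift;")
print("a high VIP flags a metabolite that drives the case/control separation,")
print("and 'direction' is the sign of its mean case Z-score.")
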
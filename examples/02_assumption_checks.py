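"""IRT assumption checks on a synthetic two-group cohort.

Generates the default school/CAP cohort from the anxiety bank, splits it in
half, and runs unidimensionality (KMO, parallel analysis, EFA), local
independence (one-factor CFA residuals), and monotonicity (Mokken H) checks.
"""

import warnings

import promis_irt as pi

bank = pi.load_item_bank("anxiety_sv")
cohort = pi.generate_cohort(bank, pi.CohortConfig(seed=1))
complete = pi.listwise_complete(cohort)
print(f"n = {cohort.n_persons}, missing {cohort.missing_fraction():.1%}, "
      f"complete n = {complete.n_persons}")

half_a, half_b = pi.split_sample(complete.n_persons, 0.5, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = pi.assumption_report(
        complete.select(complete.responses.index[half_a]),
        complete.select(complete.responses.index[half_b]),
        n_random=10, n_boot=30, seed=1,
    )

print(f"KMO overall            : {report.kmo_overall:.3f}")
print(f"eigenvalues 1, 2       : {report.eigenvalues[0]:.2f}, {report.eigenvalues[1]:.2f}"
      f"  (ratio {report.eigen_ratio_1_2:.1f})")
print(f"first-factor variance  : {report.first_factor_proportion:.2f}")
print(f"CFA fit                : " + ", ".join(f"{k.upper()} {v:.3f}"
                                               for k, v in report.fit_indices.items()))
print(f"max |residual corr|    : {report.residual_corr_max:.3f}")
print(f"scale H (SE)           : {report.h_scale:.2f} ({report.h_scale_se:.2f})")
print(f"unidimensional={report.unidimensional}, "
      f"locally_independent={report.locally_independent}, monotone={report.monotone}")
# Decision rules: >=20% first-factor variance and eigenvalue ratio > 4;
# no residual correlation above 0.20; item H > 0.30 and scale H > 0.50.
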
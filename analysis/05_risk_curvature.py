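"""Risk curvature: simulation tables and per-subject ΔR_C and σ(b_CC).

First the deterministic 2-location simulation suite (curvature vs signal
probability, ΔR_C vs prior ratio, and the ADI grid with its monotone-in-bias
/ non-monotone-in-d′ cross sections). Then, per subject: ΔR_C at the
subject's own β^s_opt and the jackknife variability of the choice-criterion
bias across blocks, correlated with the modulation indices of bias and d′.
"""

import numpy as np
import pandas as pd

from common import DESIGN, RESULTS, ensure_dirs, load_cohort
from madc.core import build_contingency_table
from madc.estimation import fit_madc
from madc.optimality import estimate_subjective_beta
from madc.psychometrics import bias_metrics_from_fit, modulation_indices
from madc.risk_curvature import (
    criterion_variability,
    leave_one_block_out_fits,
    simulate_curvature_profiles,
    subject_delta_r_c,
)
from madc.behavior_stats import percentage_bend_correlation


def main() -> None:
    ensure_dirs()
    prof = simulate_curvature_profiles(
        d_pairs=((1.0, 1.0), (2.0, 1.0)),
        prior_ratio_grid=(1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0),
        d_cued_grid=np.linspace(1.0, 5.0, 9),
    )
    prof["delta_rc_vs_ratio"].to_csv(
        RESULTS / "curvature_vs_prior_ratio.csv", index=False
    )
    prof["delta_rc_grid"].to_csv(RESULTS / "curvature_adi_grid.csv", index=False)
    eq = prof["delta_rc_vs_ratio"].query("d_cued == 1.0")
    print("simulated ΔR_C over prior ratios 1..8 (d'=1,1):",
          np.round(eq.sort_values('prior_ratio')['delta_r_c'].to_numpy(), 4))

    _, tables = load_cohort()
    rows = []
    for sid, trials in tables.items():
        tab = build_contingency_table(trials, DESIGN)
        fit = fit_madc(tab, DESIGN, seed=1, n_restarts=1)
        beta_s = estimate_subjective_beta(
            fit, DESIGN, beta_grid=np.geomspace(0.25, 4, 25),
            cost_ratio_grid=(1.0,),
        )["beta_s_opt"]
        rep = subject_delta_r_c(fit, DESIGN, beta=beta_s)
        loo = leave_one_block_out_fits(trials, DESIGN, n_restarts=0)
        var = criterion_variability(loo, DESIGN)
        bm = bias_metrics_from_fit(fit)
        d = fit.params.d_av
        rows.append(
            {"subject_id": sid, "beta_s_opt": beta_s,
             "delta_r_c": rep.delta_r_c,
             "ami_sigma_b_cc": var["ami_sigma_b_cc"],
             "adi_d": modulation_indices(d[0], d[1:]).adi,
             "adi_b_cc": modulation_indices(bm[0].b_cc, [b.b_cc for b in bm[1:]]).adi,
             "adi_b_lr": modulation_indices(bm[0].b_lr, [b.b_lr for b in bm[1:]]).adi,
             "ami_b_lr": modulation_indices(bm[0].b_lr, [b.b_lr for b in bm[1:]]).ami,
             "ami_d": modulation_indices(d[0], d[1:]).ami}
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "curvature_subjects.csv", index=False)

    for x, y in (("adi_b_lr", "delta_r_c"), ("adi_d", "delta_r_c"),
                 ("ami_b_lr", "ami_sigma_b_cc"), ("ami_d", "ami_sigma_b_cc")):
        rho, p = percentage_bend_correlation(df[x], df[y])
        print(f"{y} vs {x}: rho={rho:.2f} p={p:.3f}")


if __name__ == "__main__":
    main()
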
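"""Calibrating per-cycle transition probabilities from survival curves.

The model's transition probabilities were originally derived from trial
survival curves via log-linear regression.  Those curves are not
machine-readable, so this example simulates a Kaplan-Meier-style survival
series from a known constant hazard, fits the log-linear model, and
recovers the quarterly transition probability.
"""

from mcrc_cea import (
    fit_loglinear,
    prob_to_rate,
    rate_to_prob,
    simulate_exponential_survival,
)

# ground truth: the hazard whose quarterly death probability is 0.36
# (the best-supportive-care arm of the base case)
true_rate = prob_to_rate(0.36, 0.25)
print(f"generating hazard: {true_rate:.5f} events/year")

times = [0.25 * k for k in range(1, 9)]  # quarterly observations over 2 years

noiseless = simulate_exponential_survival(true_rate, times, noiseless=True)
exact = fit_loglinear(noiseless)
print(
    f"noiseless fit: rate {exact.rate:.5f}/yr, "
    f"quarterly probability {rate_to_prob(exact.rate, 0.25):.4f}, "
    f"R^2 {exact.r_squared:.4f}"
)

noisy = simulate_exponential_survival(true_rate, times, n_subjects=500, seed=7)
fit = fit_loglinear(noisy)
print(
    f"noisy fit (n=500): rate {fit.rate:.5f} ± {fit.stderr:.5f}/yr, "
    f"quarterly probability {rate_to_prob(fit.rate, 0.25):.4f}"
)

# On noiseless data the fit recovers the generating hazard to machine
# precision and the quarterly probability is exactly 0.36.  With binomial
# sampling noise from a 500-subject cohort the estimate deviates by a few
# percent, consistent with its reported standard error.
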
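"""Independent moment-based oracles used by the test suite only.

Closed-form method-of-moments estimates of the random-intercept model's
variance components on balanced two-trial data: the residual variance
comes from the paired differences, the between-subject variance from
the subject means after removing the trial effect.  These stay
independent of the MCMC code paths they are used to check.
"""

import numpy as np


def moment_components(ds, measure):
    """(mu, dt, sigma_s, sigma_e) moment estimates from paired data."""
    paired = ds.paired_values(measure).dropna()
    y1, y2 = paired["T1"].to_numpy(), paired["T2"].to_numpy()
    dt = float(np.mean(y2 - y1))
    sigma_e2 = float(np.var(y2 - y1, ddof=1)) / 2.0
    subj_means = (y1 + (y2 - dt)) / 2.0
    sigma_s2 = max(float(np.var(subj_means, ddof=1)) - sigma_e2 / 2.0, 0.0)
    return float(np.mean(y1)), dt, np.sqrt(sigma_s2), np.sqrt(sigma_e2)


def moment_consistency(ds, measure):
    """Moment-based dt/ICC/SEM/WSCV/SEP analogues of the Bayesian summaries."""
    mu, dt, ss, se = moment_components(ds, measure)
    total = ss**2 + se**2
    icc = ss**2 / total if total > 0 else 0.0
    return {
        "dt": dt,
        "ICC": icc,
        "SEM": se,
        "WSCV": 100.0 * se / mu,
        "SEP": np.sqrt(total) * np.sqrt(1.0 - icc**2),
    }
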
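"""Compare template and evolved strains from flask growth curves.

After an evolution run, the template and the evolved population are
regrown in shake flasks and their exponential-phase slopes compared.
Here the evolved strain grows 60% faster; the pooled log-linear
regression recovers that increment and the slope-difference t-test
confirms it at the 5% level.
"""

import numpy as np

from alesim import compare_growth
from alesim.analysis import simulate_flask_curves

rng = np.random.default_rng(3)
times = np.linspace(0, 4, 9)  # hours, exponential phase

template = simulate_flask_curves(mu=0.30, times=times, n_replicates=3,
                                 rng=rng)
evolved = simulate_flask_curves(mu=0.48, times=times, n_replicates=3,
                                rng=rng)

res = compare_growth(template, evolved, alpha=0.05)
print(f"template slope: {res.mu_a:.4f} +/- {res.mu_a_se:.4f} h^-1")
print(f"evolved slope:  {res.mu_b:.4f} +/- {res.mu_b_se:.4f} h^-1")
print(f"increment:      {res.percent_increase:+.1f}%")
print(f"slope-difference t = {res.t_statistic:.2f}, P = {res.p_value:.2e}")

# With three replicates per strain and 2% multiplicative OD noise the
# fitted slopes match the true rates, the increment sits near +60%, and
# the between-strain difference is highly significant (P << 0.05).
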
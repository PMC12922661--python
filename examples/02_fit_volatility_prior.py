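"""Fit the HGF to a session and recover the volatility prior.

Simulates a participant with a known initial volatility prior mu3_0, then
inverts the model by MAP on their choices alone. The printed estimate should
land near the generating value: the volatility prior shapes how noisily the
agent chooses, which the choice likelihood picks up.
"""

from metaprl import HGFParams, TaskConfig, default_priors, fit_map, simulate_agent

TRUE_MU3 = -1.8  # an agent that expects a fairly changeable world

params = HGFParams(mu3_0=TRUE_MU3, m3=TRUE_MU3)
session, _ = simulate_agent(params, TaskConfig(), seed=11)

fit = fit_map(session, default_priors(), n_restarts=5, seed=0)
print(f"true mu3_0:       {TRUE_MU3:+.2f}")
print(f"recovered mu3_0:  {fit.params.mu3_0:+.2f}   (MAP estimate from 160 choices)")
print(f"neg log joint:    {fit.neg_log_joint:.1f}   (lower = better fit)")
print(f"converged:        {fit.converged}")
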
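"""Simulate one participant playing the probabilistic reversal learning task.

An HGF agent with the default volatility prior plays 160 trials of the
3-option task (90-50-10 shifting to 80-40-20 at trial 81, reversals every 40
trials or after 9-of-10 best-option picks). Prints the reward rate, the
win-switch rate and where the reversals fell.
"""

from metaprl import HGFParams, TaskConfig, simulate_agent, win_switch_rate

config = TaskConfig()
session, trajectory = simulate_agent(HGFParams(), config, seed=1, participant_id="demo")

summary = win_switch_rate(session)
reversals = [(r.t, r.reversal_event) for r in session.records if r.reversal_event != "none"]

print(f"trials played:    {session.n_trials}")
print(f"reward rate:      {summary.performance:.3f}  (fraction of rewarded trials)")
print(f"win-switch rate:  {summary.wsr:.3f}  ({summary.n_win_switches}/{summary.n_win_trials} "
      "rewarded trials followed by a different choice)")
print(f"reversals:        {reversals}")
print(f"final volatility belief mu3: {trajectory.mu3[-1]:+.2f} "
      "(negative = a fairly stable world)")
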
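"""Build the ARC task design and compute the conflict statistic.

The task offers a safe $0.01 option against a risky $0.05-$0.95 option with
10/50/90% chance of aversive stimulation.  The conflict statistic
d = 0.25 - (0.5 - theta)^2 measures how close the modeled probability of
taking the risk (theta) sits to a coin flip: d is 0.25 at theta = 0.5 and 0
when the choice is certain.
"""

import numpy as np

from arcpipe import conflict, generate_design, likelihood_of_take

design = generate_design(n_trials=108, seed=1)
print("trial design:")
print(design.head(4).to_string(index=False))
print(f"... {len(design)} trials; per risk level:",
      design["risk"].value_counts().to_dict())

# an example risk-averse but reward-seeking participant
beta = np.array([1.0, -1.9, -4.2, 10.7])  # intercept, 50%-risk, 90%-risk, reward
theta = likelihood_of_take(beta, design["risk"].to_numpy(),
                           design["reward_z"].to_numpy())
d = conflict(theta)
print(f"\ntheta range across trials: [{theta.min():.3f}, {theta.max():.3f}]")
print(f"conflict d range:          [{d.min():.4f}, {d.max():.4f}] (max possible 0.25)")
imax = int(np.argmax(d))
print(f"most conflicted trial: risk={design['risk'][imax]:.0%}, "
      f"reward=${design['reward'][imax]:.2f} -> theta={theta[imax]:.3f}, d={d[imax]:.4f}")
print("high conflict arises where risk and reward nearly cancel.")
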
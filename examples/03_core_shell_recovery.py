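"""Validate an analytic form factor by refining it against bead-model data.

The virtual-experiment loop: build a multi-contrast core–shell cylinder
(core radius 20 Å, core length 360 Å, shell thickness 20 Å, core contrast
−1, shell contrast +1) from 5000 beads, simulate realistic noisy SAXS
data, then refine the closed-form core-shell-cylinder model against the
data with the core contrast held fixed at −1.  The refined geometry should
come back consistent with the values the model was built from — the
standard way to check a newly implemented analytic form factor.
"""

import sasbead as sb

result = sb.recover_core_shell_parameters(seed=1)

truth = {"r_core": 20.0, "l_core": 360.0, "t_shell": 20.0, "rho_shell": 1.0}
print("refined core-shell cylinder parameters (truth in parentheses):")
for name, true_value in truth.items():
    hat = result.params_hat[name]
    sd = result.params_sd[name]
    print(f"  {name:10s} = {hat:8.3f} +/- {sd:.3f}   ({true_value:g})")
print(f"  chi2_red   = {result.chi2_red:.3f}")
print(
    "\nEach parameter is recovered within a few standard deviations; the\n"
    "residual scatter reflects the stochastic 5000-point discretisation."
)
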
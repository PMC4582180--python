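"""Simulate a FRAP recovery curve and refit the diffusion parameters.

A GFP-tagged junction protein is photobleached on a ~3 um membrane segment;
recovery sampled every 30 s for 10 min reflects how much of the protein is
free to diffuse (mobile fraction F_m) and how fast (characteristic time
tau_D).  Complex-bound proteins recover slowly with a small mobile fraction.
"""

import sjtools as sj
from sjtools.synthetic_data import FrapSimParams

# a mutant-like fast regime: tau_D = 2.2 min, 65% mobile, realistic noise
params = FrapSimParams(tau_d=2.2 * 60, f_m=0.65, noise_sd=0.02, seed=42)
curve, truth = sj.simulate_recovery_curve(params)

fit = sj.fit_recovery(curve, bootstrap=200, seed=1)
print(f"generating truth : tau_D = {truth.tau_d/60:.2f} min, F_m = {truth.f_m:.2f}")
print(f"fitted           : tau_D = {fit.tau_d/60:.2f} min, F_m = {fit.f_m:.2f}")
print(f"half time t_1/2  : {fit.t_half/60:.2f} min (3 tau_D for this model)")
print(f"95% CI tau_D     : {fit.ci['tau_D_s'][0]/60:.2f} - {fit.ci['tau_D_s'][1]/60:.2f} min")
print(f"extrapolated     : {fit.extrapolated} (tau_D resolved within the 10-min window)")

# compare against a slow, complex-bound wild-type profile
wt_curve, _ = sj.simulate_recovery_curve(FrapSimParams(tau_d=29.5 * 60, f_m=0.29))
wt_fit = sj.fit_recovery(wt_curve)
verdict = sj.classify_mobility(wt_fit, fit)
print(f"\nwt vs mutant     : tau_D fold change {verdict.tau_fold_change:.1f}x, "
      f"delta F_m {verdict.delta_f_m:+.2f} -> {verdict.label}")
# a >=4x tau_D drop together with a >=0.10 mobile-fraction rise reads as a
# protein released from a disrupted junction complex
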
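"""FCS-style diffusion analysis of a fluctuation trace.

The multi-tau autocorrelation of the intensity decays over the diffusion
time tau_D a particle needs to cross the focus; fitting the 3D diffusion
model G(tau) = (1/N)(1 + tau/tau_D)^-1 (1 + tau/(AR^2 tau_D))^-1/2 yields
the mean occupancy N of the focal volume and tau_D, from which
D = omega^2/(8 ln2 tau_D) and, via Stokes-Einstein, the hydrodynamic size.
"""

import spp
from spp.simulate import effective_volume

omega, ar = 0.25, 5.0
d_true = 5.0                       # µm²/s, ~98-nm particle
n_eff = 1.0                        # mean particles in the focal volume
conc = n_eff / effective_volume(omega, ar)

cfg = spp.SimConfig(
    populations=[spp.Population(concentration=conc, D=d_true,
                                brightness={"g": 10.0})],
    seed=4, box=(0.6, 0.6, 2.0), bin_time=1e-5, duration=5.0)
trace, _ = spp.simulate_trace(cfg, record_transits=False)

curve = spp.autocorrelate(trace, "g")
fit = spp.fit_diffusion(curve, omega=omega, ar=ar)

print(f"G(first lag) = {curve.g[0]:.3f} -> amplitude ~ 1/N")
print(f"fitted N      = {fit.N:.2f}   (ground truth {n_eff:.2f})")
print(f"fitted tau_D  = {fit.tau_D * 1e3:.2f} ms")
print(f"D = omega^2/(8 ln2 tau_D) = {fit.D:.2f} µm²/s "
      f"(ground truth {d_true:.2f})")
print(f"hydrodynamic radius {spp.radius_from_diffusion(fit.D):.0f} nm "
      "(Stokes-Einstein, water at 25 C)")
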
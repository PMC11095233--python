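"""Track analysis of a capture video: smoothing, kinematics, capture metrics.

A 30 Hz video of an egg approaching the small magnet is synthesized with
5 um localization noise, then analyzed the way a tracked recording would
be: polynomial smoothing of x(t) with analytic differentiation, raw
finite-difference kinematics, and onset-based capture metrics.
"""

import numpy as np

import ovomag as om

scenario = om.default_scenario("S-02-02")
truth = om.simulate_scenario(scenario)

video = om.gen_capture_video(scenario, frame_rate=30.0, localization_sd=5e-6, seed=7)
print(f"video: {len(video)} frames at 30 Hz, release at {scenario.z0*1e3:.2f} mm")

# polynomial smoothing of the approach (excluding the contact corner)
approach = om.Trajectory(t=video.t[:-2], x=video.x[:-2])
fit = om.fit_polynomial(approach, degree="auto")
v_fn, a_fn = om.differentiate_fit(fit)
print(f"smoothing: degree {fit.degree}, residual sd {fit.residual_sd*1e6:.1f} um")

# raw finite differences and the position-parameterized profile
profile = om.kinematics_profile(video)
x_seg, v_of_x, a_of_x = om.profile_vs_position(profile, noise_floor=3e-4)
print(f"peak speed (finite differences): {np.abs(profile.v).max()*1e3:.1f} mm/s")

metrics = om.capture_metrics(video)
print(f"observed effective range : {metrics.effective_range_obs*1e3:.2f} mm "
      f"(release was {scenario.z0*1e3:.2f} mm)")
print(f"observed capture time    : {metrics.capture_time_obs:.2f} s "
      f"(simulator: {truth.capture_time:.2f} s)")
print("\nThe observed metrics recover the simulation ground truth to within"
      "\na few camera frames; the smoothed and finite-difference kinematics"
      "\nagree away from the contact corner.")
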
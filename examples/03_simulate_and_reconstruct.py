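"""Simulate one pearl per rotation regime and recover its kinematics.

Generates a day of rotation for each shape class, forward-models the 25
dome channels with 5% noise, reconstructs the orientation and prints the
estimated angular speed and observability.
"""

from pearlrot import (
    angular_speed,
    build_dome,
    gaussian_smooth,
    observability_score,
    reconstruct_orientation,
    simulate_recording,
    simulate_trajectory,
)

dome = build_dome()
print("class     | true speed | est speed (deg/min) | h/rev | observability")
for cls, speed in (("Round", 0.69), ("Atypical", 0.69), ("Other", 0.0)):
    traj = simulate_trajectory(cls, duration_s=86400, rate_hz=1 / 60, speed_deg_min=speed, seed=8)
    rec = simulate_recording(traj, dome, noise_frac=0.05, seed=8)
    recon = reconstruct_orientation(gaussian_smooth(rec, window=9), dome)
    est = angular_speed(recon, lag=10)  # 10-minute lag suppresses noise bias
    obs = observability_score(recon, noise_floor_deg=0.3)
    hpr = f"{est.hours_per_rev:5.1f}" if est.mean > 0.05 else "  inf"
    print(f"{cls:9s} | {speed:10.2f} | {est.mean:19.3f} | {hpr} | {obs:.2f}")
# Rotating pearls cluster near 0.69 deg/min (~8.7 h per revolution); the
# non-rotating pearl shows near-zero speed and near-zero observability.
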
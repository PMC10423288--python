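"""Build the 25-sensor dome and forward-model the magnet's dipole field.

Prints the dome layout and the field projections the sensors would read for
a magnet pointing at the zenith.
"""

import numpy as np

from pearlrot import build_dome, default_magnet_position, dipole_field

dome = build_dome()
print(f"dome radius: {dome.radius * 100:.1f} cm (4.2 L half-sphere)")
print(f"sensors: {dome.n_sensors} on rings {dome.rings} degrees")

pos = default_magnet_position(dome)
print(f"magnet position (second-ring height): z = {pos[2] * 100:.1f} cm")

moment = np.array([0.0, 0.0, 1.0])  # magnet pointing at the zenith
readings = [float(dipole_field(moment, s.position - pos) @ s.axis) for s in dome.sensors]
print("\nper-ring mean |reading| (arbitrary field units):")
for ring in dome.rings:
    vals = [abs(r) for r, s in zip(readings, dome.sensors) if s.ring == ring]
    print(f"  ring {ring:4.0f} deg: {np.mean(vals):9.1f}")
# The zenith sensor, sitting on the moment axis, reads the strongest field;
# readings fall off with distance cubed.
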
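"""Physical constants and unit conventions.

The package works in micrometres, seconds and piconewtons throughout:
lengths in um, times in s, forces in pN, torques in pN um, viscosity in
pN s um^-2 (water: 1e-3, numerically equal to Pa s). This keeps every
quantity of the problem between O(1e-5) and O(1e3).
"""

#: Boltzmann constant in pN um / K (1.380649e-23 J/K converted once;
#: 1 pN um = 1e-18 J).
K_B = 1.380649e-5

#: Dynamic viscosity of water at room temperature, pN s um^-2 (= 1e-3 Pa s).
WATER_VISCOSITY = 1.0e-3

#: Default ambient temperature, K.
ROOM_TEMPERATURE = 298.15
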
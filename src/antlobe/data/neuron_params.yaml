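# Canonical Connor-Stevens point-neuron parameter set (crustacean axon at
# 18 degC, as standardized in the common textbook formulation).  Point-neuron
# convention: conductances in mS/cm^2, currents in uA/cm^2, capacitance in
# uF/cm^2, voltages in mV, time in ms.
connor_stevens:
  capacitance: 1.0        # uF/cm^2
  g_na: 120.0             # mS/cm^2, transient sodium
  g_k: 20.0               # mS/cm^2, delayed-rectifier potassium
  g_a: 47.7               # mS/cm^2, transient A-type potassium
  g_leak: 0.3             # mS/cm^2
  e_na: 55.0              # mV
  e_k: -72.0              # mV
  e_a: -75.0              # mV
  e_leak: -17.0           # mV

# Odorant transduction: exact binding stage dx/dt = b*u*(1-x) - d*x feeding a
# saturating current map I = i_max * x / (x + k_half*(1 + gamma*z)) with one
# slow adaptation state dz/dt = (x - z)/tau_z.
otp:
  i_max: 60.0             # uA/cm^2 at full receptor occupancy
  k_half: 0.2             # occupancy at half-maximal current (unadapted)
  gamma: 0.5              # adaptation strength
  tau_z: 150.0            # ms, adaptation time constant

# Alpha synapse defaults and synapse-count scaling.  Feedforward (OSN->PN)
# synapses are fast nicotinic-like; LN-associated synapses are slower, in
# line with the sluggish local-neuron transmission of the antennal lobe.
synapse:
  g_unit: 0.0002          # mS/cm^2 of peak conductance per anatomical synapse
  tau: 5.0                # ms, alpha time-to-peak, feedforward synapses
  tau_ln: 20.0            # ms, alpha time-to-peak, LN-associated synapses
  e_rev_excitatory: 0.0   # mV
  e_rev_inhibitory: -80.0 # mV

# Presynaptic (axo-axonal) modulation of OSN terminals by LNs:
# gain = 1 / (1 + kappa * s(t)), s(t) = alpha-filtered LN spike train.
presynaptic:
  kappa_unit: 0.005       # modulation strength per anatomical synapse
  tau_mod: 50.0           # ms, filter time-to-peak

# Simulation conventions.
simulation:
  dt: 0.01                # ms
  spike_threshold: 0.0    # mV, upward crossing
  spike_lockout: 2.0      # ms, minimum inter-spike interval
  external_current_unit: 1.0  # "nA" in protocols maps to this many uA/cm^2
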
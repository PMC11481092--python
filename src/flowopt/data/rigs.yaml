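# Reactor presets. Bed void volume is 0.5 mL per 0.9 g of catalyst, scaled
# linearly with the bed loading, keeping step-1 residence times in the
# 0.5-8 min range over the flow bounds. The telescoped anhydride stock
# concentration is set by calibration (see kinetics.yaml provenance note).
osat:
  catalyst_mass: 0.9
  bed_void_volume: 0.5
  V_R2: 0.5
  pressure: 7.0
  stock_conc_1: 0.10
  stock_conc_3: 2.0
  solvent_density: 0.854
  gas_mass_rate: 0.02
telescoped:
  catalyst_mass: 1.5
  bed_void_volume: 0.8333333333333334
  V_R2: 1.5
  pressure: 7.0
  stock_conc_1: 0.035
  stock_conc_3: 0.13261114269942478
  solvent_density: 0.854
  gas_mass_rate: 0.02
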
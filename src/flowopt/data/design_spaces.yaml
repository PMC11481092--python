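# Optimization variable bounds per campaign mode (working assumptions,
# consistent with the reported optima; override via config for other rigs).
step1:
  - {name: T1, role: temperature, unit: degC, lower: 60.0, upper: 150.0}
  - {name: Q1, role: liquid_flow, unit: mL/min, lower: 0.1, upper: 1.0}
  - {name: C1, role: concentration, unit: mol/L, lower: 0.025, upper: 0.10}
step2:
  - {name: T2, role: temperature, unit: degC, lower: 30.0, upper: 100.0}
  - {name: tau2, role: residence_time, unit: min, lower: 0.5, upper: 5.0}
  - {name: equiv, role: flow_ratio, unit: ratio, lower: 1.0, upper: 3.0}
step2-im:
  - {name: T2, role: temperature, unit: degC, lower: 30.0, upper: 100.0}
  - {name: tau2, role: residence_time, unit: min, lower: 0.5, upper: 5.0}
  - {name: equiv, role: flow_ratio, unit: ratio, lower: 1.0, upper: 3.0}
telescoped:
  - {name: T1, role: temperature, unit: degC, lower: 60.0, upper: 150.0}
  - {name: T2, role: temperature, unit: degC, lower: 30.0, upper: 100.0}
  - {name: Q1, role: liquid_flow, unit: mL/min, lower: 0.1, upper: 1.0}
  - {name: ratio, role: flow_ratio, unit: ratio, lower: 2.0, upper: 10.0}
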
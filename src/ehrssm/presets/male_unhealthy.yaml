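# Unhealthy lifestyle preset (male): sudden corruption of body composition
# from the first check-up year onward. Values are raw units.
label: male_unhealthy
base: actual
overrides:
  "Abdominal Circumference": {value: 95, start: 1}
  "Waist / Hip Ratio": {value: 1.05, start: 1}
  "Body Mass Index": {value: 30, start: 1}
  "Current Smoking Habits": {value: 1, start: 1}
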
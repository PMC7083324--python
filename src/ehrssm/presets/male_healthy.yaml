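# Healthy lifestyle preset (male): improvement of body composition from the
# first check-up year onward. Values are raw units.
label: male_healthy
base: actual
overrides:
  "Abdominal Circumference": {value: 75, start: 1}
  "Waist / Hip Ratio": {value: 0.80, start: 1}
  "Body Mass Index": {value: 20, start: 1}
  "Current Smoking Habits": {value: 0, start: 1}
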
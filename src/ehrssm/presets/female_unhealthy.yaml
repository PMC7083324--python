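# Unhealthy lifestyle preset (female). Values are raw units.
label: female_unhealthy
base: actual
overrides:
  "Waist / Hip Ratio": {value: 0.95, start: 1}
  "Body Mass Index": {value: 30, start: 1}
  "Body Fat Percentage": {value: 35, start: 1}
  "Current Smoking Habits": {value: 1, start: 1}
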
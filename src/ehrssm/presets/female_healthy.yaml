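# Healthy lifestyle preset (female): non-smoking, non-drinking, daily
# exercise. Values are raw units.
label: female_healthy
base: actual
overrides:
  "Waist / Hip Ratio": {value: 0.70, start: 1}
  "Body Mass Index": {value: 20, start: 1}
  "Body Fat Percentage": {value: 20, start: 1}
  "Current Smoking Habits": {value: 0, start: 1}
  "Current Drinking Habits": {value: 0, start: 1}
  "Averaged Exercise Hours": {value: 5, start: 1}
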
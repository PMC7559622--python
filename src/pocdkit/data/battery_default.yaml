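# Default six-test neuropsychological battery.
# orientation: +1 higher score = better performance, -1 higher = worse
# (time/latency-based instruments).
tests:
  - {name: visual_verbal_learning, orientation: 1}
  - {name: concept_shifting, orientation: -1}
  - {name: stroop, orientation: -1}
  - {name: memory_scanning, orientation: -1}
  - {name: letter_digit, orientation: -1}
  - {name: reaction_time, orientation: -1}
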
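# Benchmark and innovation scenarios for the sequential-treatment cascade:
# a 100-patient cohort treated until >99% have responded, compared by
# excess treatments (total minus cohort size) against the declining
# baseline (50% first-step response, 10% geometric decline per step).
cohort_size: 100
coverage_target: 0.99
rounding: per_step_half_up
baseline: declining-baseline
scenarios:
  constant-42:
    schedule: {kind: constant, first_response: 0.42, max_steps: 100}
  declining-baseline:
    schedule: {kind: geometric_decline, first_response: 0.50, decline_rate: 0.10, max_steps: 100}
  first-step-smd-0.45:
    schedule: {kind: geometric_decline, first_response: 0.50, decline_rate: 0.10, max_steps: 100}
    improvements:
      - {scope: first_step_only, smd_delta: 0.15}
  all-steps-smd-0.45:
    schedule: {kind: geometric_decline, first_response: 0.50, decline_rate: 0.10, max_steps: 100}
    improvements:
      - {scope: all_steps, smd_delta: 0.15}
  all-steps-doubled:
    schedule: {kind: geometric_decline, first_response: 0.50, decline_rate: 0.10, max_steps: 100}
    improvements:
      - {scope: all_steps, point_gain: 0.14}
  trd-step3-restored:
    schedule: {kind: geometric_decline, first_response: 0.50, decline_rate: 0.10, max_steps: 100}
    improvements:
      - {scope: single_step, step_index: 3, replacement_p: 0.50}
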
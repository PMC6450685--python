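# Default analysis configuration. Every key is optional; omitted keys take
# the documented package defaults. Unknown keys are rejected at load time.
generator:
  n_animals: 9
  sessions_per_animal: 3
  neurons_per_session_mean: 117.0
  neurons_per_session_sd: 8.0
  frame_rate: 20.0
  trials_per_stimulus: 10

pre_s: 5.0
post_s: 10.0
response_window: [0.0, 2.0]
n_shuffles: 1000
q_threshold: 0.05
k_folds: 5
n_repeats: 10
z_active: 2.0
registration_max_distance_px: 5.0
reflex_window: [0.0, 1.0]
affective_window: [1.0, 10.0]
seed: 1
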
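# Demonstration pipeline: small enough to fit encoding models end to end.
out_dir: scratch/pipeline_demo
bootstrap_b: 200
predictions: models
encode_rois: [hc_l_1, hc_r_1, hc_l_4, hc_r_4, calcarine_l, calcarine_r]
sim:
  n_subjects: 4
  n_images: 30
  images_per_run: 10
  n_runs_encode: 3
  channels_per_layer: 3
  n_vertices_per_roi: 8
  n_movie_samples: 40
  seed: 20
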
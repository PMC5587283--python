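{
 "seed": 5,
 "out_dir": "demo_out",
 "alpha": 0.05,
 "groups": [
  {"genotype": "mdx", "age_months": 3, "region": "midcostal"},
  {"genotype": "control", "age_months": 3, "region": "midcostal"}
 ],
 "source": {
  "mode": "synthetic_images",
  "n_longitudinal": 2,
  "n_section": 2,
  "striation": {"image_shape": [384, 384]},
  "section": {"n_fibers": 24, "pixel_size_um": 0.5, "image_shape": [384, 384]}
 }
}
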
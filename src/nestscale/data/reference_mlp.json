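{
 "layer_sizes": [9, 3, 1],
 "hidden_weights": [
  [1.202640, 2.025155, -2.773383],
  [-0.059006, 0.280633, 0.211419],
  [-0.419412, 1.299244, -0.838220],
  [-0.442465, 0.771556, -0.075977],
  [0.964739, 2.033089, 0.465052],
  [-0.226521, 0.920540, -0.065647],
  [0.288798, 2.659565, -0.522707],
  [0.210606, 0.844355, 0.106924],
  [0.759511, 1.367401, 0.129165]
 ],
 "hidden_biases": [-0.967833, -0.247893, 3.395910],
 "output_weights": [2.357087, 3.643371, -4.810658],
 "output_bias": -0.778603,
 "resample_factor": 300.0,
 "input_scaling": {"weight_divisor": 300.0, "count_divisor": 2048.0},
 "sigmoid_orientation": "standard"
}
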
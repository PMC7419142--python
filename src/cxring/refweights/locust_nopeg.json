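{
 "variant": "locust_nopeg",
 "species": "locust",
 "sigma": 0.8,
 "drop_peg": true,
 "weights": {
  "w1": 4.0345264348383205,
  "w2": 1.3418652502377313,
  "w3": 4.9608052408720305,
  "w4": -13.453467999338244,
  "w5": -0.9176399768399277
 },
 "peak_rate_epg": 247.59302528897962,
 "peak_rate_pen": null,
 "method": "pso",
 "seed": 5,
 "budget": 1000,
 "objective": 0.6209174827705596,
 "accepted": true
}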
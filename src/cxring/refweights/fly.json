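{
 "variant": "fly",
 "species": "fly",
 "sigma": 0.8,
 "drop_peg": false,
 "weights": {
  "w1": 1.9913502323287902,
  "w2": 1.875025976871527,
  "w3": 3.117137492339876,
  "w4": -1.9541338282492429,
  "w5": -1.5610310529893734
 },
 "peak_rate_epg": 302.0810995427346,
 "peak_rate_pen": 94.57467239946803,
 "method": "pso",
 "seed": 11,
 "budget": 1000,
 "objective": 0.16323452371649974,
 "accepted": true
}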
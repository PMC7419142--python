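{
 "variant": "fly_nopeg",
 "species": "fly",
 "sigma": 0.8,
 "drop_peg": true,
 "weights": {
  "w1": 2.905986412783258,
  "w2": 1.455681406921311,
  "w3": 2.7457302434092736,
  "w4": -0.7055932795388328,
  "w5": -2.541686287362703
 },
 "peak_rate_epg": 275.18271023597936,
 "peak_rate_pen": null,
 "method": "pso",
 "seed": 34,
 "budget": 1000,
 "objective": 0.7155204897127252,
 "accepted": false
}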
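{
 "variant": "hybrid",
 "species": "hybrid",
 "sigma": 0.8,
 "drop_peg": false,
 "weights": {
  "w1": 1.6695148153163166,
  "w2": 0.9142038172102576,
  "w3": 2.0384224170382357,
  "w4": -6.273946078157856,
  "w5": 0.0
 },
 "peak_rate_epg": 300.3168266075723,
 "peak_rate_pen": 137.59011036936246,
 "method": "pso",
 "seed": 43,
 "budget": 2000,
 "objective": 1.5429916344210592,
 "accepted": true
}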
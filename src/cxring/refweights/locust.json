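{
 "variant": "locust",
 "species": "locust",
 "sigma": 0.8,
 "drop_peg": false,
 "weights": {
  "w1": 2.0043279839323485,
  "w2": 1.0508021173276227,
  "w3": 1.5058167746751763,
  "w4": -25.399440579918604,
  "w5": -0.5774441092571062
 },
 "peak_rate_epg": 283.08077619658457,
 "peak_rate_pen": 230.88339240594058,
 "method": "pso",
 "seed": 2,
 "budget": 1000,
 "objective": 0.6639396327916468,
 "accepted": true
}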
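{
 "single_cable": {
  "n_segments": 4,
  "tau": [
   1.0,
   0.0,
   0.0
  ],
  "fa_t": 1.0,
  "line_length": 10.0
 },
 "branched_toy": {
  "n_segments": 4,
  "tau": [
   0.529903603582,
   0.456756745308,
   0.01333965111
  ],
  "fa_t": 0.691927296827,
  "line_length": 10.0
 },
 "isotropic_tree": {
  "n_segments": 91,
  "tau": [
   0.356530392749,
   0.335877254579,
   0.307592352672
  ],
  "fa_t": 0.073570899286,
  "line_length": 10.0
 },
 "aligned_tree": {
  "n_segments": 92,
  "tau": [
   0.994051896213,
   0.003215426828,
   0.002732676959
  ],
  "fa_t": 0.996999257957,
  "line_length": 10.0
 },
 "bundle_k5": {
  "n_segments": 300,
  "tau": [
   0.770278593892,
   0.128118315579,
   0.10160309053
  ],
  "fa_t": 0.832847531187,
  "line_length": 10.0
 }
}
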
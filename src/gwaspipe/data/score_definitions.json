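{
  "version": "1.0",
  "east_asian": {
    "terms": [
      ["rs9269027", "A", 0.69173],
      ["rs1974461", "T", 1.23685],
      ["rs6707458", "G", 0.36687],
      ["rs230540", "C", 0.25098],
      ["rs9405192", "G", 0.39127]
    ],
    "interactions": [
      ["rs9269027", "rs6707458", 0.48798]
    ],
    "control_mean": 1.6804,
    "control_sd": 1.0033,
    "crs": {
      "weight": 1.7712,
      "control_mean": 0.3724,
      "control_sd": 2.7503,
      "offset": 0.001
    }
  },
  "european": {
    "terms": [
      ["rs9271541", "C", 0.34945],
      ["rs9265949", "T", 0.67919],
      ["rs2858309", "C", 0.30707],
      ["rs6707458", "G", 0.34601],
      ["rs230540", "C", 0.17450],
      ["rs9405192", "G", 0.18343]
    ],
    "interactions": [
      ["rs9271541", "rs6707458", 0.33782]
    ],
    "control_mean": 1.5089,
    "control_sd": 0.8202,
    "crs": {
      "weight": 0.4829,
      "control_mean": -1.4982,
      "control_sd": 1.4354,
      "offset": 0.001
    }
  }
}
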
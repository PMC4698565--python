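{
  "W136": {
    "printed_label_prefix": "W136",
    "printed_average": 0.0134,
    "lower_triangle": [
      [0.0019],
      [0.0196, 0.0216],
      [0.0019, 0.0039, 0.0177],
      [0.0216, 0.0236, 0.0058, 0.0196],
      [0.0058, 0.0078, 0.0176, 0.0039, 0.0196],
      [0.0117, 0.0137, 0.0157, 0.0098, 0.0098, 0.0098],
      [0.0182, 0.0202, 0.0223, 0.0162, 0.0202, 0.0162, 0.0141],
      [0.0216, 0.0236, 0.0058, 0.0196, 0.0, 0.0196, 0.0098, 0.0202],
      [0.0019, 0.0039, 0.0177, 0.0, 0.0196, 0.0039, 0.0098, 0.0162, 0.0196]
    ]
  },
  "W202": {
    "printed_label_prefix": "W202",
    "printed_average": 0.0135,
    "lower_triangle": [
      [0.0139],
      [0.0200, 0.0157],
      [0.0142, 0.022, 0.0140],
      [0.0119, 0.0059, 0.0119, 0.0259],
      [0.0139, 0.0, 0.0157, 0.0219, 0.0059],
      [0.0139, 0.0, 0.0157, 0.0219, 0.0059, 0.0],
      [0.0122, 0.0239, 0.0160, 0.0061, 0.0239, 0.0239, 0.0239],
      [0.0119, 0.0019, 0.0137, 0.0199, 0.0078, 0.0019, 0.0019, 0.0219],
      [0.0100, 0.0176, 0.0177, 0.0080, 0.0176, 0.0176, 0.0176, 0.0060, 0.0157]
    ]
  },
  "V145": {
    "printed_label_prefix": "V145",
    "printed_average": 0.0056,
    "lower_triangle": [
      [0.0019],
      [0.0078, 0.0059],
      [0.0078, 0.0059, 0.0],
      [0.0059, 0.0039, 0.0019, 0.0019],
      [0.0059, 0.0059, 0.0078, 0.0059, 0.0078],
      [0.0078, 0.0098, 0.0078, 0.0078, 0.0078, 0.0137],
      [0.0019, 0.0, 0.0059, 0.0059, 0.0039, 0.0059, 0.0098],
      [0.0039, 0.0019, 0.0039, 0.0039, 0.0059, 0.0019, 0.0117, 0.0019],
      [0.0059, 0.0039, 0.0078, 0.0059, 0.0078, 0.0039, 0.0137, 0.0039, 0.0019]
    ]
  },
  "Z704": {
    "printed_label_prefix": "Z704",
    "printed_average": 0.0072,
    "lower_triangle": [
      [0.0019],
      [0.0019, 0.0],
      [0.0019, 0.0, 0.0],
      [0.0098, 0.0078, 0.0078, 0.0078],
      [0.0098, 0.0078, 0.0078, 0.0078, 0.0],
      [0.0117, 0.0098, 0.0098, 0.0098, 0.0019, 0.0019],
      [0.0039, 0.0019, 0.0019, 0.0019, 0.0059, 0.0059, 0.0078],
      [0.0039, 0.0019, 0.0019, 0.0019, 0.0059, 0.0059, 0.0078, 0.0],
      [0.0141, 0.0162, 0.0162, 0.0162, 0.0162, 0.0162, 0.0182, 0.0182, 0.0182]
    ]
  },
  "W127": {
    "printed_label_prefix": "V127",
    "printed_average": 0.0177,
    "lower_triangle": [
      [0.0101],
      [0.0289, 0.0307],
      [0.0267, 0.0328, 0.0083],
      [0.0122, 0.0141, 0.0368, 0.0246],
      [0.0041, 0.0101, 0.0267, 0.0205, 0.0121],
      [0.0144, 0.0246, 0.0083, 0.0083, 0.0266, 0.0185],
      [0.0165, 0.0266, 0.0104, 0.0104, 0.0246, 0.0246, 0.0146],
      [0.0226, 0.0328, 0.0083, 0.0041, 0.0287, 0.0267, 0.0083, 0.0104],
      [0.0124, 0.0226, 0.0104, 0.0104, 0.0267, 0.0165, 0.0021, 0.0167, 0.0104]
    ]
  }
}
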
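{
  "description": "Blue-tit-like tetrachromat receptor set (synthetic Gaussian stand-in; peaks near published blue tit cone maxima, widths and abundances rounded) and a UV-converted-DSLR-like six-channel camera spanning 320-690 nm.",
  "synthetic": true,
  "receptors": {
    "UV": {
      "peak": 372.0,
      "width": 18.0
    },
    "SW": {
      "peak": 449.0,
      "width": 22.0
    },
    "MW": {
      "peak": 503.0,
      "width": 28.0
    },
    "LW": {
      "peak": 563.0,
      "width": 32.0
    },
    "D": {
      "peak": 563.0,
      "width": 60.0
    }
  },
  "abundances": {
    "UV": 0.37,
    "SW": 0.7,
    "MW": 0.99,
    "LW": 1.0,
    "D": 1.0
  },
  "weber_fraction": 0.05,
  "camera": {
    "uvB": {
      "peak": 340.0,
      "width": 20.0
    },
    "uvR": {
      "peak": 380.0,
      "width": 22.0
    },
    "visB": {
      "peak": 455.0,
      "width": 35.0
    },
    "visG": {
      "peak": 520.0,
      "width": 35.0
    },
    "visR": {
      "peak": 585.0,
      "width": 35.0
    },
    "visR2": {
      "peak": 650.0,
      "width": 40.0
    }
  }
}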
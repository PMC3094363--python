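{
  "name": "default",
  "terminal": "total tree",
  "steps": [
    {"op": "add", "inputs": ["stem wood", "stem bark"], "output": "bole"},
    {"op": "add", "inputs": ["branches total", "foliage"], "output": "crown (branches + foliage)"},
    {"op": "or", "alternatives": ["crown (branches + foliage)", "live crown"], "output": "live crown f"},
    {"op": "add", "inputs": ["bole", "live crown f"], "output": "aboveground (bole + crown)"},
    {"op": "or", "alternatives": ["aboveground (bole + crown)", "aboveground total"], "output": "aboveground f"},
    {"op": "add", "inputs": ["aboveground f", "roots coarse"], "output": "total tree"}
  ]
}
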
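{
  "284470004": "S",
  "63593006": "S",
  "427172004": "V",
  "17338001": "V",
  "164884008": "V",
  "426761007": "SVTA",
  "49260003": "IVR"
}
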
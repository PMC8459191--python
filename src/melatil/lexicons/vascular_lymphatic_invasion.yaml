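feature: vascular_lymphatic_invasion
heads:
  - '(?:vascular|lymphatic)\s*(?:or\s+|/\s*)?(?:vascular|lymphatic)?\s*invasion'
  - 'lymph(?:o|-)?vascular\s+invasion'
  - 'angiolymphatic\s+invasion'
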
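{
  "non_systemic": [],
  "diagnostic": [],
  "withdrawn": [],
  "pk_implausible": [],
  "known_ineffective_or_aggravating": []
}
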
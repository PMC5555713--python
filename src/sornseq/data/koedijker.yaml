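# Canonical 8-button finger-tapping sequences.  Each pair differs at exactly
# two buttons: positions 4 and 5 for the first pair, 4 and 7 for the second.
pairs:
  buttons_4_5:
    alphabet: [I, D, F, B, K, H, A, L, J, C]
    sequences:
      S1: [I, D, F, B, K, H, A, L]
      S2: [I, D, F, J, C, H, A, L]
  buttons_4_7:
    alphabet: [I, D, F, C, E, G, J, H, K, B]
    sequences:
      S1: [I, D, F, C, E, G, J, H]
      S2: [I, D, F, K, E, G, B, H]
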
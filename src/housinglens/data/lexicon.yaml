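# Seed lexicon for housing-related keyword matching and window-based
# qualification. All matching is token-sequence based, case-insensitive.
# Sites extend these lists via a run-config override; entries must be
# lowercase.
window: 6

terms:
  - homeless
  - homelessness
  - unhoused
  - unstable housing
  - housing insecure
  - housing insecurity
  - housing instability
  - living on the streets
  - lack of housing

# cues honored before the match
negation_pre:
  - denies
  - denied
  - "no evidence of"
  - not
  - never
  - without
  - "negative for"

# cues honored before OR after the match ("... homeless and she denied")
negation_post:
  - denies
  - denied

history_cues:
  - "history of"
  - "years ago"
  - previously
  - formerly
  - "in the past"

third_party_cues:
  - "found a"
  - "her boyfriend"
  - "his girlfriend"
  - "her husband"
  - "his wife"
  - "family member"
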
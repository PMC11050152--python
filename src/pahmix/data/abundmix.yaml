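# AbundMix: the six most abundant PAHs from the same air sample.
# No TEFs are assigned to these components, so only the uM dose axis
# is available for this mixture.
name: AbundMix
full_strength_total: 100.0
components:
  - component: naphthalene
    proportion_percent: 44
  - component: acenaphthene
    proportion_percent: 18.3
  - component: 2-methylnaphthalene
    proportion_percent: 15.9
  - component: 1-methylnaphthalene
    proportion_percent: 11.9
  - component: fluorene
    proportion_percent: 6.7
  - component: phenanthrene
    proportion_percent: 3.16
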
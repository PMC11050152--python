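# ToxMix: the seven most toxic PAHs from a creosote-site air sample,
# at environmentally relevant ratios, with toxic equivalency factors
# (benzo[e]pyrene reference).
name: ToxMix
full_strength_total: 100.0   # uM of the 100% mixture (configurable stand-in)
components:
  - component: retene
    proportion_percent: 68.6
    tef: 0.001
  - component: benzo[a]fluorene
    proportion_percent: 16.8
    tef: 0.001
  - component: benzo[b]fluorene
    proportion_percent: 8.42
    tef: 0.001
  - component: benzo[c]fluorene
    proportion_percent: 4.21
    tef: 0.001
  - component: triphenylene
    proportion_percent: 1.68
    tef: 0.001
  - component: benzo[e]pyrene
    proportion_percent: 0.168
    tef: 1
  - component: benzo[ghi]perylene
    proportion_percent: 0.0842
    tef: 0.01
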
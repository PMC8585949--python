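# Feed-resource conversion parameters: proper-use fraction (maximum share of the
# standing resource that can be taken without degrading it) and metabolizable-energy
# content (MJ ME per kg DM, min/avg/max) per feed class, plant part and, where the
# values differ between the two agro-ecological zones, per zone.
#
# Browse proper use follows the take-70%/leave-30% rule combined with the 55%
# availability factor: 0.70 x 0.55 = 0.385, shipped truncated to 0.38.
# Residues lose nutritive value in storage (decay_per_month, compounding) and
# managed rotational grazing raises pasture productivity by the grazing_uplift.
grazing_uplift: 0.076      # forage only, dimensionless
decay_per_month: 0.08      # crop residues only, per month after harvest
feeds:
  - {feed_class: forage, part: whole, zone: sahelian, proper_use: 0.55, me_min: 5.8, me_avg: 6.1, me_max: 6.4}
  - {feed_class: forage, part: whole, zone: sudanian, proper_use: 0.55, me_min: 6.2, me_avg: 6.5, me_max: 6.8}
  - {feed_class: browse, part: whole, zone: sahelian, proper_use: 0.38, me_min: 5.8, me_avg: 6.0, me_max: 6.2}
  - {feed_class: browse, part: whole, zone: sudanian, proper_use: 0.38, me_min: 8.0, me_avg: 8.1, me_max: 8.2}
  - {feed_class: residue_groundnut, part: whole, zone: any, proper_use: 1.00, me_min: 7.2, me_avg: 8.5, me_max: 9.3}
  - {feed_class: residue_maize, part: stem, zone: any, proper_use: 0.10, me_min: 5.7, me_avg: 6.0, me_max: 6.3}
  - {feed_class: residue_maize, part: leaf, zone: any, proper_use: 0.76, me_min: 5.9, me_avg: 7.1, me_max: 8.3}
  - {feed_class: residue_millet, part: stem, zone: any, proper_use: 0.10, me_min: 5.2, me_avg: 5.6, me_max: 6.0}
  - {feed_class: residue_millet, part: leaf, zone: any, proper_use: 0.76, me_min: 6.8, me_avg: 8.1, me_max: 9.4}
  - {feed_class: residue_sorghum, part: stem, zone: any, proper_use: 0.10, me_min: 5.9, me_avg: 6.2, me_max: 6.5}
  - {feed_class: residue_sorghum, part: leaf, zone: any, proper_use: 0.76, me_min: 5.9, me_avg: 6.4, me_max: 6.9}
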
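"""Seasonal energy requirement of herd categories and the per-TLU average.

Prints the wet/dry season metabolizable-energy requirement (MER) breakdown of
one cow in the Sudanian zone (maintenance dominates; the dry season subtracts
a mobilization credit for the ~12% bodyweight cattle lose), then the annual
requirement per head of each species and per Tropical Livestock Unit (250 kg
reference animal) for the default herd mix.
"""
from sahelcc import HerdParams, seasonal_category_demand
from sahelcc.calibrate import demand_per_head

herd = HerdParams.default()
for season, days in (("wet", 183), ("dry", 182)):
    r = seasonal_category_demand(herd, "cattle", "cow", season, days, "sudanian")
    print(f"cow, {season} season ({days} d): maintenance {r['mer_m']:7.0f}  growth {r['mer_g']:5.0f}  "
          f"lactation {r['mer_l']:5.0f}  travel {r['mer_t']:6.0f}  "
          f"- credit {r['mobilization_credit']:5.0f}  = {r['mer_total']:7.0f} MJ")

per_head = demand_per_head(herd)
mix = {"cattle": 1.0, "sheep": 0.6, "goat": 0.8}
print("\nannual MER per head (Sudanian zone seasons):")
for sp in mix:
    print(f"  {sp:7s}: {per_head[('sudanian', sp)]:7.0f} MJ/yr  ({herd.tlu_per_head(sp):.3f} TLU/head)")
d = sum(mix[sp] * per_head[("sudanian", sp)] for sp in mix)
t = sum(mix[sp] * herd.tlu_per_head(sp) for sp in mix)
print(f"herd-mix demand per TLU: {d / t:7.0f} MJ/TLU/yr  (FAO-consistent band: 8000-12000)")
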
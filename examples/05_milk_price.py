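"""Back-of-envelope consumer cost of the intervention.

Derives the average retail price of milk per 100 g from national annual
sales and shipment volume, then the extra daily spending needed for a
person to move from their current intake to 180 g/day.
"""

from milkstroke.economics import estimate_purchase_cost, milk_retail_price
from milkstroke.parameters import load_parameter_set

price = milk_retail_price(total_sales_usd=3.86e9, shipment_volume_kl=3_211_400)
print(f"Average retail price: USD {price:.4f} per 100 g (~{price:.2f})")

params = load_parameter_set("paper2023")
for stratum, p in sorted(params.strata.items(), key=lambda kv: (kv[0].sex.value, kv[0].age_band)):
    extra = estimate_purchase_cost(price, p.dairy_intake_mean, 180.0)
    print(
        f"{stratum.sex.value:5s} {stratum.age_band}: +{180.0 - p.dairy_intake_mean:5.1f} g/day "
        f"-> USD {extra:.4f}/day"
    )
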
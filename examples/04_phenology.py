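"""Monthly and seasonal bloom area of mass-flowering crops.

Spreads each crop's planted area uniformly over its bloom months and sums
by month and season.  Crop areas and bloom windows are user inputs; these
are illustrative values.
"""

from floralwastage import generate_crop_table, monthly_bloom_area, seasonal_totals
from floralwastage.synthetic import CropSpec

crops = generate_crop_table(
    crops=[
        CropSpec("oilseed rape", 364_000, 4, 6),
        CropSpec("field bean", 170_000, 6, 7),
        CropSpec("field pea", 50_000, 6, 7),
        CropSpec("orchard fruit", 25_000, 4, 5),
    ]
)
monthly = monthly_bloom_area(crops)
print("area in bloom per month (thousand ha):")
print((monthly / 1000).round(1).to_string())
print()
seasons = seasonal_totals(monthly)
print("seasonal totals (thousand ha):")
print((seasons / 1000).round(1).to_string())
# Conservation: the monthly contributions of each crop sum exactly to its
# planted area, so the season totals sum to total planted area.
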
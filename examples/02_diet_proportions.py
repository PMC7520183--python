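"""From read counts to diet proportions, order lumping and salmon split.

A two-scat toy table is normalized to proportions, lumped into taxonomic
orders, and the salmonid share is split into juvenile and adult
pseudo-orders using a month-scope hard-part ratio.
"""
import pandas as pd

from dietspec import diet
from dietspec.io import load_annotation_fixture

annotation = load_annotation_fixture()
counts = pd.DataFrame(
    {"Clupea pallasii": [1200, 0],
     "Oncorhynchus tshawytscha": [800, 300],
     "Gadus macrocephalus": [0, 2700]},
    index=pd.Index(["scat1", "scat2"], name="sample_id"))

props = diet.to_proportions(counts)
orders = diet.aggregate_orders(props, annotation)
print("species proportions:\n", props.round(3))
print("order proportions:\n", orders.round(3))

# Hard parts say 25% of Chinook in scat1's stratum were juveniles
ratios = pd.DataFrame([
    {"sample_id": "scat1", "taxon": "Oncorhynchus tshawytscha",
     "juvenile_fraction": 0.25},
    {"sample_id": "scat2", "taxon": "Oncorhynchus tshawytscha",
     "juvenile_fraction": 0.25}])
split = diet.split_salmonids(orders, props, annotation, ratios)
print("with juvenile/adult split:\n",
      split[["Salmoniformes", diet.JUVENILE_ORDER, diet.ADULT_ORDER]].round(3))
# scat1: Chinook is 0.4 of the diet, so juvenile = 0.4*0.25 = 0.1 and
# adult = 0.3; the two pseudo-orders always sum back to Salmoniformes.
print("benthic fraction per scat:\n",
      diet.benthic_fraction(props, annotation).round(3))
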
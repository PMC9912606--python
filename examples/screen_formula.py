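"""ADME-screen the bundled nine-herb decoction table and list shared ingredients.

The package ships the published OB / Caco-2 / DL table of the Di-Tan
decoction (196 herb-ingredient rows).  We screen it with the standard
cutoffs (OB >= 30%, Caco-2 > -0.4, DL >= 0.18) and count the ingredients
that appear in two or more herbs — multi-herb ingredients are candidate
carriers of the formula's shared pharmacology.
"""

from fcig.screen import adme_screen, load_dtt_ingredients, shared_ingredients, specific_ingredients

table = load_dtt_ingredients()
active = adme_screen(table)
shared = shared_ingredients(table)
specific = specific_ingredients(table)

print(f"herb-ingredient rows:            {len(table)}")
print(f"rows passing the ADME screen:    {len(active)}")
print(f"ingredients shared by >=2 herbs: {len(shared)}")
print(f"single-herb ingredients:         {len(specific)}")
print()
print(shared[["ingredient_id", "name", "n_herbs", "herbs"]].to_string(index=False))
print()
print("Each row above is one compound found in several of the formula's "
      "herbs; beta-sitosterol (MOL000358) spans five of them.")
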
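# Survey food-group codebook, version 1.
#
# This 20-group instrument is a RECONSTRUCTION: the original per-country food
# lists are not published, so the survey groups here are identified with the
# 20 diet-quality (PDQS) groups, each carrying its dietary-diversity (MDD-W)
# destination group.  Labels are configurable; ids are fixed.
#
# mddw_group: null means the group does not count toward the 10-group
# dietary diversity score (oils, sweet beverages, desserts have no MDD-W home).
version: 1
note: >-
  Reconstructed instrument: survey groups coincide with the 20 PDQS groups.
  Adaptations baked in: no fried-foods-away-from-home group; dairy rather than
  low-fat dairy; roots and tubers in place of potatoes; red/orange produce
  folded into other vitamin A-rich fruits and vegetables; maize-flour products
  counted as refined grains.
groups:
  - id: dark_green_leafy_vegetables
    label: Dark green leafy vegetables
    mddw_group: vitamin_a_dark_green_vegetables
    healthy: true
  - id: other_vitamin_a_fruits_vegetables
    label: Other vitamin A-rich fruits and vegetables (incl. red/orange produce)
    mddw_group: other_vitamin_a_fruits_vegetables
    healthy: true
  - id: cruciferous_vegetables
    label: Cruciferous vegetables
    mddw_group: other_vegetables
    healthy: true
  - id: other_vegetables
    label: Other vegetables
    mddw_group: other_vegetables
    healthy: true
  - id: citrus_fruits
    label: Whole citrus fruits
    mddw_group: other_fruits
    healthy: true
  - id: other_fruits
    label: Other fruits
    mddw_group: other_fruits
    healthy: true
  - id: fish
    label: Fish
    mddw_group: meat_poultry_fish
    healthy: true
  - id: eggs
    label: Eggs
    mddw_group: eggs
    healthy: true
  - id: poultry
    label: Poultry
    mddw_group: meat_poultry_fish
    healthy: true
  - id: legumes
    label: Legumes (beans, peas, lentils)
    mddw_group: legumes
    healthy: true
  - id: nuts_seeds
    label: Nuts and seeds
    mddw_group: nuts_seeds
    healthy: true
  - id: dairy
    label: Dairy
    mddw_group: dairy
    healthy: true
  - id: whole_grains
    label: Whole grains
    mddw_group: grains_roots_tubers
    healthy: true
  - id: liquid_vegetable_oils
    label: Liquid vegetable oils
    mddw_group: null
    healthy: true
  - id: red_meat
    label: Red meat
    mddw_group: meat_poultry_fish
    healthy: false
  - id: processed_meats
    label: Processed meats
    mddw_group: meat_poultry_fish
    healthy: false
  - id: refined_grains
    label: Refined grains and baked goods (incl. maize-flour products)
    mddw_group: grains_roots_tubers
    healthy: false
  - id: sugar_sweetened_beverages
    label: Sugar-sweetened beverages
    mddw_group: null
    healthy: false
  - id: desserts_ice_cream
    label: Desserts and ice cream
    mddw_group: null
    healthy: false
  - id: roots_tubers
    label: Potatoes, roots and tubers
    mddw_group: grains_roots_tubers
    healthy: false
# Survey groups excluded from scoring at specific sites (local food lists).
site_masks:
  Kersa:
    - other_vitamin_a_fruits_vegetables
  AddisAbaba:
    - citrus_fruits
    - other_fruits
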
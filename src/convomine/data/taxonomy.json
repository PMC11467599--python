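{
  "burn_injury": [
    "burn", "burns", "burned", "burnt", "scald", "scalded",
    "sunburn", "sunburned", "sunburnt"
  ],
  "fa_general": [
    "treatment", "treat", "remedy", "cure", "first aid",
    "1st aid", "advice", "medicine", "heal", "soothe"
  ],
  "fa_specific": [
    "water", "tap", "shower", "ice", "frozen peas", "compress",
    "wet cloth", "wet towel", "aloe", "moisturiser", "e45",
    "aftersun", "lotion", "calamine", "gel", "sudocrem", "savlon",
    "germaline", "acriflex", "cream", "vaseline", "ibuprofen",
    "aspirin", "paracetamol", "clingfilm"
  ],
  "fa_food": [
    "butter", "margarine", "oil", "honey", "egg", "yoghurt",
    "potato", "onion", "turmeric", "flour", "milk"
  ],
  "children": [
    "my kid", "little one", "infant", "child", "toddler", "kiddo",
    "youngster", "year old", "yo", "month old", "mo old", "baby",
    "babbie", "babe", "bub", "bairn"
  ],
  "exclusion": [
    "out", "down", "calories", "calorie", "energy", "hell",
    "bridges", "ground", "house"
  ]
}
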
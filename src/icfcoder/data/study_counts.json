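{
  "MOBILITY": {
    "n_documents": 289,
    "n_documents_with_mentions": 251,
    "n_mentions": 2455,
    "n_mentions_with_action": 2323,
    "n_actions": 3176,
    "n_train_documents": 203,
    "n_train_actions": 2361,
    "n_test_documents": 45,
    "n_test_actions": 815,
    "iaa_f1": 0.778,
    "categories": {
      "d450": {"count": 730, "train": 559, "test": 171},
      "d410": {"count": 560, "train": 419, "test": 141},
      "d415": {"count": 508, "train": 385, "test": 123},
      "d440": {"count": 319, "train": 247, "test": 72},
      "d430": {"count": 244, "train": 167, "test": 77},
      "d475": {"count": 215, "train": 165, "test": 50},
      "d445": {"count": 163, "train": 104, "test": 59},
      "d455": {"count": 147, "train": 99, "test": 48},
      "OTHER": {"count": 123, "train": 96, "test": 27},
      "d470": {"count": 103, "train": 80, "test": 23},
      "d460": {"count": 55, "train": 34, "test": 21},
      "d435": {"count": 5, "train": 4, "test": 1},
      "d420": {"count": 4, "train": 2, "test": 2}
    }
  },
  "SELFCARE_DOMESTIC": {
    "n_documents": 329,
    "n_documents_with_mentions": 285,
    "n_mentions": 3990,
    "n_mentions_with_action": 3866,
    "n_actions": 4665,
    "n_train_documents": 229,
    "n_train_actions": 3350,
    "n_test_documents": 56,
    "n_test_actions": 1315,
    "iaa_f1": 0.695,
    "categories": {
      "d570": {"count": 2032, "train": 1496, "test": 536},
      "MANAGE_MED": {"count": 520, "train": 359, "test": 161},
      "d540": {"count": 353, "train": 268, "test": 85},
      "d520": {"count": 312, "train": 228, "test": 84},
      "d640": {"count": 297, "train": 205, "test": 92},
      "d630": {"count": 222, "train": 165, "test": 57},
      "OTHER": {"count": 174, "train": 127, "test": 47},
      "THERAPY": {"count": 143, "train": 103, "test": 40},
      "d620": {"count": 142, "train": 101, "test": 41},
      "d510": {"count": 121, "train": 90, "test": 31},
      "d550": {"count": 102, "train": 57, "test": 45},
      "d560": {"count": 82, "train": 60, "test": 22},
      "d660": {"count": 79, "train": 46, "test": 33},
      "d650": {"count": 40, "train": 24, "test": 16},
      "d530": {"count": 29, "train": 15, "test": 14},
      "d610": {"count": 17, "train": 6, "test": 11}
    }
  }
}
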
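[
 {"name": "score_a", "origin": "variant", "group": "pathogenic_score", "subgroup": "pathogenic_score", "tissue_tag": null, "impute_value": 0.1, "dtype": "numeric"},
 {"name": "score_b", "origin": "variant", "group": "pathogenic_score", "subgroup": "pathogenic_score", "tissue_tag": null, "impute_value": 0.5, "dtype": "numeric"},
 {"name": "consequence__missense", "origin": "variant", "group": "consequence", "subgroup": "consequence", "tissue_tag": null, "impute_value": 0.0, "dtype": "indicator"},
 {"name": "consequence__synonymous", "origin": "variant", "group": "consequence", "subgroup": "consequence", "tissue_tag": null, "impute_value": 0.0, "dtype": "indicator"},
 {"name": "consequence__stop_gained", "origin": "variant", "group": "consequence", "subgroup": "consequence", "tissue_tag": null, "impute_value": 0.0, "dtype": "indicator"},
 {"name": "expr__heart", "origin": "tissue", "group": "expression", "subgroup": "expression", "tissue_tag": "heart", "impute_value": 0.0, "dtype": "numeric"},
 {"name": "expr__whole_brain", "origin": "tissue", "group": "expression", "subgroup": "expression", "tissue_tag": "whole_brain", "impute_value": 0.0, "dtype": "numeric"}
]
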
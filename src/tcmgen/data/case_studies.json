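{
  "case1": {
    "label": ["Photinia serratifolia", "Dried Zingiber", "Scutellaria baicalensis georgi", "Asarum", "dried Rehmannia glutinosa", "Ligusticum chuanxiong Hort", "Panax ginseng", "ephedra", "peeled cinnamomum cassia", "Angelica sinensis", "Glycyrrhiza", "Zanthoxylum ailanthoides"],
    "label_score": 8.5,
    "predictions": {
      "KDHR": ["Photinia serratifolia", "Saposhnikovia divaricata", "Anemarrhena asphodeloides Bunge", "Akebia quinata", "Cynanchum otophyllum", "Poria cocos", "Cimicifuga foetida", "dendrobium", "Bupleurum", "Gardenia jasminoides", "Rehmannia glutinosa", "Ziziphus jujuba", "Atractylodes macrocephala", "Houpoea officinalis", "Mentha", "Pueraria lobata", "Citrus reticulata", "Tribulus terrestris", "Panax notoginseng", "Arctium lappa", "Fallopia multiflora"],
      "PTM": ["Photinia serratifolia", "Zingiber", "Saposhnikovia divaricata", "Perilla frutescens", "Phellodendron", "corydalis yanhusuo", "Corydalis decumbens", "Coptis chinensis", "curcuma", "roasted Zingiber"],
      "Coverage-Soft-Model": ["Photinia serratifolia", "Phellodendron", "folium pini", "aconitum kusnezoffii", "Arctium lappa", "Codonopsis pilosula", "Mylabris", "Aconitum carmichaeli", "Bambusa basihirsuta McClure"],
      "Herb-Know": ["Photinia serratifolia", "Scutellaria baicalensis georgi", "Anemarrhena asphodeloides Bunge", "Asarum", "Atractylodes macrocephala", "roasted Zingiber", "Achyranthes bidentata", "Corydalis decumbens", "Saposhnikovia divaricata", "Coptis chinensis", "Tribulus terrestris", "Alumen", "Pinellia ternate", "Nepeta cataria", "Pericarpium Citrus reticulata"],
      "TPGen": ["Photinia serratifolia", "Zingiber", "Scutellaria baicalensis georgi", "Pinellia ternate", "Ziziphus jujuba", "Pericarpium Citrus reticulata", "Angelica sinensis", "Corydalis yanhusuo", "Dendrobium", "Panax notoginseng"],
      "GSCCAM": ["Photinia serratifolia", "Cinnamomi Ramulus", "Angelica sinensis", "Glycyrrhiza", "Zingiber", "Nepeta cataria", "Scutellaria baicalensis georgi", "Asarum", "Panax ginseng", "dried Rehmannia glutinosa", "Zanthoxylum ailanthoides", "Saposhnikovia divaricata", "Angelica dahurica"]
    },
    "scores": {"KDHR": 3.9, "PTM": 5.1, "Coverage-Soft-Model": 3.5, "Herb-Know": 5.7, "TPGen": 5.4, "GSCCAM": 7.6}
  },
  "case2": {
    "label": ["Areca catechu", "old zingiber", "Aconitum carmichaeli", "Poria cocos", "Evodia rutaecarpa", "Pericarpium Citri reticulata", "peeled cinnamomum cassia", "Platycodon grandiflorus", "Atractylodes macrocephala"],
    "label_score": 8.8,
    "predictions": {
      "KDHR": ["Areca catechu", "Aconitum carmichaeli", "Cinnamomum cassia", "Dimocarpus longan", "roasted Zingiber", "curcuma", "Bupleurum", "dried Zingiber", "Dendrobium", "Panax ginseng", "Citrus medica", "Perilla frutescens", "chrysanthemum", "Mentha", "Houpoea officinalis"],
      "PTM": ["Areca catechu", "Zingiber", "Cinnamomi Ramulus", "dried Zingiber", "Eucommia ulmoides", "Cinnamomum cassia", "Lycium barbarum"],
      "Coverage-Soft-Model": ["Areca catechu", "Zingiber", "Syzygium aromaticum", "Cinnamomum cassia", "Curcuma", "Ephedra", "Asarum"],
      "Herb-Know": ["Areca catechu", "Zingiber", "Aconitum carmichaeli", "Poria cocos", "Cynanchum otophyllum", "Astragalus membranaceus", "Eucommia ulmoides", "Citrus medica", "Lycium barbarum", "Cassia tora", "Dendrobium"],
      "TPGen": ["Areca catechu", "Lycium barbarum", "dried zingiber", "Aconitum carmichaeli", "Pericarpium Citri reticulata", "Ziziphus jujuba", "Dioscoreae", "aconitum"],
      "GSCCAM": ["Areca catechu", "Platycodon grandiflorus", "Zingiber", "Aconitum carmichaeli", "Poria cocos", "Cinnamomi Ramulus", "Pericarpium Citri reticulata", "Astragalus membranaceus", "Evodia rutaecarpa"]
    },
    "scores": {"KDHR": 4.3, "PTM": 5.5, "Coverage-Soft-Model": 4.0, "Herb-Know": 5.6, "TPGen": 5.8, "GSCCAM": 7.8}
  },
  "benchmark": {
    "KDHR": {"precision": 0.2041, "recall": 0.1473, "f1": 0.1711},
    "PTM": {"precision": 0.1982, "recall": 0.1536, "f1": 0.1731},
    "Coverage-Soft-Model": {"precision": 0.1844, "recall": 0.1073, "f1": 0.1357},
    "Herb-Know": {"precision": 0.3082, "recall": 0.2101, "f1": 0.2499},
    "TPGen": {"precision": 0.2794, "recall": 0.2291, "f1": 0.2518},
    "GSCCAM": {"precision": 0.3739, "recall": 0.2504, "f1": 0.2999}
  }
}
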
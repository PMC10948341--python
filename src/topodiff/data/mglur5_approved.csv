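drug_id,name,ba_kcal_mol
DB12301,Doravirine,-10.52
DB00304,Desogestrel,-10.05
DB12612,Ozanimod,-9.90
DB01595,Nitrazepam,-9.87
DB06636,Isavuconazonium,-9.85
DB09291,Rolapitant,-9.78
DB08439,Parecoxib,-9.75
DB00294,Etonogestrel,-9.73
DB00475,Chlordiazepoxide,-9.72
DB11633,Isavuconazole,-9.68
DB00404,Alprazolam,-9.65
DB00904,Ondansetron,-9.63
DB15685,Selpercatinib,-9.62
DB11374,Amprolium,-9.57
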
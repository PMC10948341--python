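drug_id,name,ba_kcal_mol
DB12703,Omipalisib,-13.06
DB11896,Gedatolisib,-12.36
DB13109,PKI-179,-12.34
DB11836,Sapanisertib,-12.20
DB12774,AZD-8055,-11.74
DB11925,Vistusertib,-11.50
DB13072,GDC-0349,-11.24
DB06233,Ridaforolimus,-11.21
DB12570,CC-223,-11.01
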
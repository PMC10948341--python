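drug_id,name,ba_kcal_mol
DB13004,Mavoglurant,-10.88
DB12733,Dipraglurant,-10.82
DB11649,Lersivirine,-10.40
DB12999,MK-6186,-10.17
DB15406,GLPG-0974,-10.11
DB04885,Cilansetron,-10.11
DB14929,Elsulfavirine,-10.10
DB13035,AG-24322,-10.02
DB12931,Fenobam,-10.01
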
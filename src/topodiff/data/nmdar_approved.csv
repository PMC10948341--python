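drug_id,name,ba_kcal_mol
DB00157,NADH,-10.10
DB03147,FAD,-10.09
DB00705,Delavirdine,-9.75
DB00131,Adenosine phosphate,-9.69
DB00118,Ademetionine,-9.61
DB00364,Sucralfate,-9.56
DB08874,Fidaxomicin,-9.56
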
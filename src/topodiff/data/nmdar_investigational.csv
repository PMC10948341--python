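drug_id,name,ba_kcal_mol
DB06741,Gavestinel,-11.70
DB12365,Perzinfotel,-10.84
DB12749,Butylphthalide,-10.47
DB05553,Regrelor,-10.23
DB12140,Dilmapimod,-10.14
DB03708,Adenosine 5'-phosphosulfate,-10.12
DB13019,Henatinib,-9.92
DB06334,Tucidinostat,-9.84
DB12012,PF-04457845,-9.83
DB05973,Inosine 5'-sulfate,-9.79
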
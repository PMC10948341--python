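drug_id,name,ba_kcal_mol
DB00877,Sirolimus,-12.46
DB00864,Tacrolimus,-12.32
DB01590,Everolimus,-12.07
DB00337,Pimecrolimus,-11.39
DB12483,Copanlisib,-10.40
DB11943,Delafloxacin,-10.31
DB09272,Eluxadoline,-10.31
DB01764,Dalfopristin,-10.12
DB00705,Delavirdine,-10.07
DB00709,Lamivudine,-10.05
DB00615,Rifabutin,-10.04
DB00879,Emtricitabine,-9.92
DB00210,Adapalene,-9.91
DB12153,Citicoline,-9.87
DB12767,Gaxilose,-9.84
DB13274,Micronomicin,-9.72
DB06725,Lornoxicam,-9.61
DB08907,Canagliflozin,-9.59
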
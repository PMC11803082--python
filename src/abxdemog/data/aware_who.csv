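drug,category
Amoxicillin,Access
Amoxicillin/clavulanic acid,Access
Phenoxymethylpenicillin,Access
Benzylpenicillin,Access
Flucloxacillin,Access
Ampicillin,Access
Pivmecillinam,Access
Nitrofurantoin,Access
Trimethoprim,Access
Sulfamethoxazole/trimethoprim,Access
Doxycycline,Access
Tetracycline,Access
Oxytetracycline,Access
Metronidazole,Access
Clindamycin,Access
Gentamicin,Access
Cefalexin,Access
Cefradine,Access
Cefadroxil,Access
Chloramphenicol,Access
Clarithromycin,Watch
Azithromycin,Watch
Erythromycin,Watch
Ciprofloxacin,Watch
Levofloxacin,Watch
Moxifloxacin,Watch
Ofloxacin,Watch
Norfloxacin,Watch
Lymecycline,Watch
Minocycline,Watch
Cefaclor,Watch
Cefuroxime,Watch
Cefixime,Watch
Fosfomycin,Watch
Fusidic acid,Watch
Vancomycin,Watch
Teicoplanin,Watch
Rifampicin,Watch
Neomycin,Watch
Colistin,Reserve
Linezolid,Reserve
Cefiderocol,Reserve
Dalbavancin,Reserve
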
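source_name,reference_name
Flucloxacillin sodium,Flucloxacillin
Flucloxacillin magnesium,Flucloxacillin
Doxycycline hyclate,Doxycycline
Doxycycline monohydrate,Doxycycline
Penicillin V,Phenoxymethylpenicillin
Penicillin V potassium,Phenoxymethylpenicillin
Co-amoxiclav,Amoxicillin/clavulanic acid
Co-trimoxazole,Sulfamethoxazole/trimethoprim
Pivmecillinam hydrochloride,Pivmecillinam
Erythromycin ethylsuccinate,Erythromycin
Erythromycin stearate,Erythromycin
Erythromycin lactobionate,Erythromycin
Colistimethate sodium,Colistin
Ciprofloxacin hydrochloride,Ciprofloxacin
Minocycline hydrochloride,Minocycline
Oxytetracycline dihydrate,Oxytetracycline
Amoxicillin trihydrate,Amoxicillin
Amoxicillin sodium,Amoxicillin
Cephalexin,Cefalexin
Vancomycin hydrochloride,Vancomycin
Fosfomycin trometamol,Fosfomycin
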
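name,formula,compound_class,role,reference_rt,fragments,semi_quant_reference,provenance,flag
caftaric acid,C13H12O9,phenolic acid,suspect,2.80,293.0303;267.0510,gallic acid,grape suspect literature; synthetic RT and fragments,
gallocatechin,C15H14O7,flavonoid,suspect,3.00,287.0561;261.0768,catechin,grape suspect literature; synthetic RT and fragments,
coutaric acid,C13H12O8,phenolic acid,suspect,3.60,277.0354;251.0561,gallic acid,grape suspect literature; synthetic RT and fragments,reported class direction contradicts reported values (17.6 vs 87.7 mg/kg); both kept verbatim
p-hydroxybenzoic acid,C7H6O3,phenolic acid,suspect,3.80,119.0139;93.0346,gallic acid,grape suspect literature; synthetic RT and fragments,
fraxin,C16H18O10,coumarin,suspect,4.40,351.0722;325.0929,vanillin,grape suspect literature; synthetic RT and fragments,
chicoric acid,C22H18O12,phenolic acid,suspect,4.90,455.0620;429.0827;311.0197,gallic acid,grape suspect literature; synthetic RT and fragments,
ellagic acid hexoside,C20H16O13,phenolic acid,suspect,5.20,445.0412;419.0620;300.9990,gallic acid,grape suspect literature; synthetic RT and fragments,
procyanidin B1,C30H26O12,flavonoid,suspect,5.40,559.1246;533.1453;415.0823,catechin,grape suspect literature; synthetic RT and fragments,
epigallocatechin gallate,C22H18O11,flavonoid,suspect,5.45,439.0671;413.0878,catechin,grape suspect literature; synthetic RT and fragments,
procyanidin A1,C30H24O12,flavonoid,suspect,6.50,557.1089;531.1297;413.0667,catechin,grape suspect literature; synthetic RT and fragments,
ellagic acid,C14H6O8,phenolic acid,suspect,6.60,282.9884;257.0092,gallic acid,grape suspect literature; synthetic RT and fragments,
miquelianin,C21H18O13,flavonoid glycoside,suspect,6.62,459.0569;433.0776;315.0146,rutin,grape suspect literature; synthetic RT and fragments,
rutin,C27H30O16,flavonoid glycoside,suspect,7.00,591.1355;565.1563;447.0933,rutin,grape suspect literature; synthetic RT and fragments,also a target standard; reported once with both roles
trans-piceid,C20H22O8,stilbene,suspect,7.20,371.1136;345.1344,quercetin,grape suspect literature; synthetic RT and fragments,
quercetin-3-O-glucoside,C21H20O12,flavonoid glycoside,suspect,7.40,445.0776;419.0984;301.0354,rutin,grape suspect literature; synthetic RT and fragments,
quercetin-3-O-galactoside,C21H20O12,flavonoid glycoside,suspect,7.45,445.0776;419.0984;301.0354,rutin,grape suspect literature; synthetic RT and fragments,isobaric with quercetin-3-O-glucoside
trans-resveratrol,C14H12O3,stilbene,suspect,9.80,209.0608;183.0815,quercetin,grape suspect literature; synthetic RT and fragments,
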
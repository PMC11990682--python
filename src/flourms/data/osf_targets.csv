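name,formula,compound_class,role,reference_rt,fragments,semi_quant_reference,provenance,flag
gallic acid,C7H6O5,phenolic acid,target,1.60,151.0037;125.0244,,target standard list; synthetic RT and fragments,
protocatechuic acid,C7H6O4,phenolic acid,target,3.30,135.0088;109.0295,,target standard list; synthetic RT and fragments,
epigallocatechin,C15H14O7,flavonoid,target,3.90,287.0561;261.0768,,target standard list; synthetic RT and fragments,
caffeic acid,C9H8O4,phenolic acid,target,4.20,161.0244;135.0452,,target standard list; synthetic RT and fragments,
catechin,C15H14O6,flavonoid,target,4.50,271.0612;245.0819,,target standard list; synthetic RT and fragments,
vanillic acid,C8H8O4,phenolic acid,target,4.80,149.0244;123.0452,,target standard list; synthetic RT and fragments,
vanillin,C8H8O3,phenol,target,5.10,133.0295;107.0502,,target standard list; synthetic RT and fragments,
epicatechin,C15H14O6,flavonoid,target,5.60,271.0612;245.0819,,target standard list; synthetic RT and fragments,
coumaric acid,C9H8O3,phenolic acid,target,5.90,145.0295;119.0502,,target standard list; synthetic RT and fragments,
epicatechin gallate,C22H18O10,flavonoid,target,6.10,423.0722;397.0929,,target standard list; synthetic RT and fragments,
sinapic acid,C11H12O5,phenolic acid,target,6.35,205.0506;179.0714,,target standard list; synthetic RT and fragments,
ferulic acid,C10H10O4,phenolic acid,target,6.70,175.0401;149.0608,,target standard list; synthetic RT and fragments,
myricitrin,C21H20O12,flavonoid glycoside,target,6.80,445.0776;419.0984;301.0354,,target standard list; synthetic RT and fragments,
rutin,C27H30O16,flavonoid glycoside,target,7.00,591.1355;565.1563;447.0933,,target standard list; synthetic RT and fragments,
taxifolin,C15H12O7,flavonoid,target,7.30,285.0405;259.0612,,target standard list; synthetic RT and fragments,
diosmin,C28H32O15,flavonoid glycoside,target,7.60,589.1563;563.1770;445.1140,,target standard list; synthetic RT and fragments,
myricetin,C15H10O8,flavonoid,target,7.75,299.0197;273.0405,,target standard list; synthetic RT and fragments,
hesperidin,C28H34O15,flavonoid glycoside,internal_standard,7.90,591.1719;565.1927;447.1297,,target standard list; synthetic RT and fragments,
quercitrin,C21H20O11,flavonoid glycoside,target,8.05,429.0827;403.1035;285.0405,,target standard list; synthetic RT and fragments,
luteolin,C15H10O6,flavonoid,target,8.40,267.0299;241.0506,,target standard list; synthetic RT and fragments,
quercetin,C15H10O7,flavonoid,target,8.90,283.0248;257.0455,,target standard list; synthetic RT and fragments,
naringenin,C15H12O5,flavonoid,target,9.20,253.0506;227.0714,,target standard list; synthetic RT and fragments,enumerated name without a listed standard (naringin supplied instead); excluded from the default spike set
kaempferol,C15H10O6,flavonoid,target,9.60,267.0299;241.0506,,target standard list; synthetic RT and fragments,
apigenin,C15H10O5,flavonoid,target,10.10,251.0350;225.0557,,target standard list; synthetic RT and fragments,
chrysin,C15H10O4,flavonoid,target,11.00,235.0401;209.0608,,target standard list; synthetic RT and fragments,
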